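"""Helpers shared by test modules (not fixtures)."""
import numpy as np

from mibci import (EventList, SimConfig, bandpass, extract_epochs,
                   generate_recording, resample, segment_windows)
from mibci.features_td import extract_td_features


def localized_erd_features(seed: int):
    """Features from a simulation whose only ERD is mu attenuation at C3."""
    cfg = SimConfig(n_sessions=1, trials_per_task=6, seed=seed,
                    erd_depth={"MI-GRASP": {"C3": {"mu": 0.6}}},
                    artifact_rate=0.0)
    rec, ev = generate_recording(cfg)
    rec = bandpass(resample(rec, 250.0), 6.0, 35.0)
    onsets = np.round(ev.onsets / 4).astype(np.int64)
    epochs = extract_epochs(rec, EventList(onsets, ev.labels), 1.0, 3.0)
    return extract_td_features(segment_windows(epochs, 1.0))
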