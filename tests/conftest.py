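"""Shared fixtures: small simulated datasets reused across test modules."""
import numpy as np
import pytest

from mibci import (EventList, SimConfig, extract_epochs, bandpass,
                   generate_recording, resample, segment_windows)
from mibci.features_td import extract_td_features
from mibci.sim import default_erd_depth


def simulate_features(depth: float, seed: int, n_sessions: int = 2,
                      trials_per_task: int = 10):
    """Full preprocessing chain on a simulated recording -> FeatureMatrix."""
    cfg = SimConfig(n_sessions=n_sessions, trials_per_task=trials_per_task,
                    seed=seed, erd_depth=default_erd_depth(depth))
    rec, ev = generate_recording(cfg)
    rec = bandpass(resample(rec, 250.0), 6.0, 35.0)
    onsets = np.round(ev.onsets * 250.0 / cfg.fs).astype(np.int64)
    epochs = extract_epochs(rec, EventList(onsets, ev.labels), 1.0, 3.0)
    segs = segment_windows(epochs, 1.0)
    return epochs, extract_td_features(segs)


@pytest.fixture(scope="session")
def small_sim():
    """One short session (5 trials per task) with mid-strength ERD."""
    cfg = SimConfig(n_sessions=1, trials_per_task=5, seed=42,
                    erd_depth=default_erd_depth(0.5))
    return cfg, *generate_recording(cfg)


@pytest.fixture(scope="session")
def small_epochs(small_sim):
    cfg, rec, ev = small_sim
    rec = bandpass(resample(rec, 250.0), 6.0, 35.0)
    onsets = np.round(ev.onsets / 4).astype(np.int64)
    return extract_epochs(rec, EventList(onsets, ev.labels), 1.0, 3.0)


@pytest.fixture(scope="session")
def small_segments(small_epochs):
    return segment_windows(small_epochs, 1.0)


@pytest.fixture(scope="session")
def small_features(small_segments):
    return extract_td_features(small_segments)
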