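"""On-disk interchange: EDF recordings, event sidecars, segment tables.

Recordings are written as plain EDF (16-bit, one data record per second)
by a minimal writer implemented here, and read back through MNE's EDF
reader. Events travel in a CSV sidecar (onset_sample, onset_s, label);
epoch/segment sets are persisted as a long-format CSV (instance, channel,
sample, value) with a JSON manifest for labels and window metadata.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet, EventList, Recording, SegmentSet

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r}")
    return b.ljust(width)


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as EDF (one 1 s data record per second, padded).

    The sampling rate must be a positive integer (samples per 1 s record).
    Each channel is scaled to the 16-bit digital range over a symmetric
    physical range covering its data.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :rec.n_samples] = rec.data

    phys_max = np.ceil(np.abs(padded).max(axis=1)) + 1.0
    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field(f"Startdate 01-JAN-2000 ref:{rec.reference_label}", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (n_ch + 1)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    labels = [_field(lbl, 16) for lbl in rec.channel_labels]
    transducer = [_field("AgAgCl electrode", 80)] * n_ch
    dim = [_field("uV", 8)] * n_ch
    pmin = [_field(f"{-m:.0f}", 8) for m in phys_max]
    pmax = [_field(f"{m:.0f}", 8) for m in phys_max]
    dmin = [_field(str(_DIG_MIN), 8)] * n_ch
    dmax = [_field(str(_DIG_MAX), 8)] * n_ch
    prefilter = [_field("", 80)] * n_ch
    spr = [_field(str(fs), 8)] * n_ch
    reserved = [_field("", 32)] * n_ch
    sig_header = b"".join(b"".join(block) for block in
                          (labels, transducer, dim, pmin, pmax, dmin, dmax,
                           prefilter, spr, reserved))

    scale = (_DIG_MAX - _DIG_MIN) / (2.0 * phys_max)
    digital = np.round((padded + phys_max[:, None]) * scale[:, None]
                       + _DIG_MIN).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (microvolts) via MNE."""
    import mne
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def write_events_csv(events: EventList, fs: float, path: str | Path) -> None:
    pd.DataFrame({
        "onset_sample": events.onsets,
        "onset_s": events.onsets / fs,
        "label": events.labels,
    }).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> EventList:
    df = pd.read_csv(path)
    return EventList(df["onset_sample"].to_numpy(np.int64),
                     df["label"].to_numpy(object))


def write_segments_csv(segs: EpochSet, path: str | Path) -> None:
    """Persist an epoch/segment set as long-format CSV plus JSON manifest."""
    path = Path(path)
    n_i, n_c, n_s = segs.data.shape
    df = pd.DataFrame({
        "instance": np.repeat(np.arange(n_i), n_c * n_s),
        "channel": np.tile(np.repeat(np.arange(n_c), n_s), n_i),
        "sample": np.tile(np.arange(n_s), n_i * n_c),
        "value": segs.data.ravel(),
    })
    df.to_csv(path, index=False)
    manifest = {
        "fs": segs.fs,
        "window": list(segs.window),
        "channel_labels": list(segs.channel_labels),
        "labels": [str(l) for l in segs.labels],
    }
    if isinstance(segs, SegmentSet):
        manifest["parent_trial"] = segs.parent_trial.tolist()
    path.with_suffix(".json").write_text(json.dumps(manifest))


def read_segments_csv(path: str | Path) -> EpochSet:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    n_i = int(df["instance"].max()) + 1
    n_c = len(manifest["channel_labels"])
    n_s = int(df["sample"].max()) + 1
    data = df["value"].to_numpy().reshape(n_i, n_c, n_s)
    labels = np.array(manifest["labels"], object)
    window = tuple(manifest["window"])
    if "parent_trial" in manifest:
        return SegmentSet(data, manifest["fs"], labels, window,
                          manifest["channel_labels"],
                          parent_trial=np.array(manifest["parent_trial"]))
    return EpochSet(data, manifest["fs"], labels, window,
                    manifest["channel_labels"])
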