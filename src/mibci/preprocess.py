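"""Resampling, band-pass filtering, epoching and window segmentation.

The standard motor-imagery chain: down-sample the raw recording to 250 Hz,
zero-phase band-pass to 6-35 Hz (covering the mu and beta rhythms while
suppressing slow ocular components), cut trial epochs around cue onsets,
then slice each epoch into fixed 1 s analysis windows.

Conventions: 0-based sample indices, half-open windows [start, stop).
"""
from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EpochSet, EventList, Recording, SegmentSet

logger = logging.getLogger(__name__)


def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias filter and decimate to ``target_fs`` (polyphase).

    Only down-sampling with a rational rate ratio is supported; requesting a
    rate above the recording's raises.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > rec.fs:
        raise ValueError("upsampling is not supported")
    if target_fs == rec.fs:
        return Recording(rec.data.copy(), rec.fs, list(rec.channel_labels),
                         rec.reference_label)
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    if abs(float(ratio) * rec.fs - target_fs) > 1e-9 * target_fs:
        raise ValueError("fs ratio is not rational within tolerance")
    data = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator,
                                axis=1)
    return Recording(data, target_fs, list(rec.channel_labels),
                     rec.reference_label)


def bandpass(rec: Recording, lo: float, hi: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    A 4th-order design run through ``sosfiltfilt`` keeps the 8-30 Hz
    passband flat while strongly attenuating DC and slow drifts, without
    phase-distorting the mu/beta rhythms.
    """
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError("band edges must satisfy 0 < lo < hi < fs/2")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs,
                        output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(data, rec.fs, list(rec.channel_labels),
                     rec.reference_label)


def extract_epochs(rec: Recording, events: EventList, t_start_s: float,
                   t_end_s: float) -> EpochSet:
    """Cut one epoch per event over ``[onset + t_start, onset + t_end)``.

    Events whose window falls outside the recording are dropped with a
    warning; an error is raised only if nothing remains.
    """
    if t_end_s <= t_start_s:
        raise ValueError("t_end_s must exceed t_start_s")
    off0 = int(round(t_start_s * rec.fs))
    n_win = int(round((t_end_s - t_start_s) * rec.fs))
    epochs, labels = [], []
    for onset, label in zip(events.onsets, events.labels):
        start = int(onset) + off0
        stop = start + n_win
        if start < 0 or stop > rec.n_samples:
            logger.warning("dropping event at sample %d: window [%d, %d) "
                           "outside recording", onset, start, stop)
            continue
        epochs.append(rec.data[:, start:stop])
        labels.append(label)
    if not epochs:
        raise ValueError("all events fell outside the recording")
    return EpochSet(np.stack(epochs), rec.fs, np.array(labels, object),
                    (t_start_s, t_end_s), list(rec.channel_labels))


def segment_windows(ep: EpochSet, win_s: float,
                    stride_s: float | None = None) -> SegmentSet:
    """Slice every epoch into fixed windows (non-overlapping by default).

    Each window becomes an independent classification instance carrying its
    parent trial's label and index.
    """
    win = int(round(win_s * ep.fs))
    stride = win if stride_s is None else int(round(stride_s * ep.fs))
    if win > ep.n_samples:
        raise ValueError("window exceeds epoch duration")
    if stride < 1:
        raise ValueError("stride must be positive")
    starts = range(0, ep.n_samples - win + 1, stride)
    data, labels, parents = [], [], []
    for t in range(ep.n_trials):
        for s in starts:
            data.append(ep.data[t, :, s:s + win])
            labels.append(ep.labels[t])
            parents.append(t)
    return SegmentSet(np.stack(data), ep.fs, np.array(labels, object),
                      (0.0, win / ep.fs), list(ep.channel_labels),
                      parent_trial=np.array(parents))
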