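"""Time-domain features: AR(4) coefficients, waveform length, RMS.

Per channel and per 1 s analysis window, six numbers are extracted: the
four coefficients of a fourth-order autoregressive model, the root mean
square amplitude, and the waveform length (cumulative absolute first
difference). With 20 channels this yields 120 features per window.

AR coefficients follow the prediction-form sign convention

    t_n = a_1 t_{n-1} + ... + a_p t_{n-p} + e_n,

and are estimated with Burg's method, which minimizes the combined
forward-backward prediction error and remains stable on short (250-sample)
EEG windows where Yule-Walker estimates degrade.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import FeatureMatrix, SegmentSet

logger = logging.getLogger(__name__)


@dataclass
class ARModel:
    """Autoregressive model in prediction form (see module docstring)."""

    order: int
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        if self.order < 1 or len(self.coefficients) != self.order:
            raise ValueError("order must be >= 1 and match coefficients")


def burg(series: np.ndarray, p: int) -> np.ndarray:
    """Burg AR coefficient estimate, prediction-form signs.

    Implements the lattice recursion: at each stage the reflection
    coefficient minimizing the summed forward and backward residual power
    is computed, and the error filter polynomial is updated by the
    Levinson step.
    """
    x = np.asarray(series, dtype=float)
    # error filter A(z) = 1 + a1 z^-1 + ... ; prediction coeffs are -a
    a = np.array([1.0])
    ef = x.copy()
    eb = x.copy()
    for m in range(p):
        f = ef[m + 1:]
        b = eb[m:-1]
        den = f @ f + b @ b
        if den <= 0:
            k = 0.0
        else:
            k = -2.0 * (b @ f) / den
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([[0.0], a[::-1]])
        ef_new = f + k * b
        eb_new = b + k * f
        ef = np.concatenate([ef[:m + 1], ef_new])
        eb = np.concatenate([eb[:m + 1], eb_new])
    return -a[1:]


def fit_ar(series: np.ndarray, p: int) -> ARModel:
    """Fit an order-``p`` AR model by Burg's method.

    Raises on constant (zero-variance) input, where the model is undefined.
    """
    x = np.asarray(series, dtype=float)
    if p < 1:
        raise ValueError("order must be >= 1")
    if len(x) <= 2 * p:
        raise ValueError("series must be longer than 2p samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    if np.ptp(x) == 0:
        raise ValueError("degenerate series: zero variance")
    return ARModel(p, burg(x, p))


def waveform_length(series: np.ndarray) -> float:
    """Sum of absolute successive differences (N-1 terms for N samples)."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("series must have at least 2 samples")
    return float(np.abs(np.diff(x)).sum())


def rms(series: np.ndarray) -> float:
    """Root mean square amplitude."""
    x = np.asarray(series, dtype=float)
    if len(x) == 0:
        raise ValueError("series must be non-empty")
    return float(np.sqrt(np.mean(x * x)))


def feature_names(channel_labels: list[str], p: int = 4) -> list[str]:
    """Channel-major column names: AR1..ARp, RMS, WL per channel."""
    names = []
    for ch in channel_labels:
        names.extend(f"{ch}/AR{i}" for i in range(1, p + 1))
        names.append(f"{ch}/RMS")
        names.append(f"{ch}/WL")
    return names


def extract_td_features(segs: SegmentSet, p: int = 4) -> FeatureMatrix:
    """Extract AR(p) + RMS + WL per channel for every analysis window.

    Constant (zero-variance) channel windows, where the AR fit is
    undefined, fall back to AR coefficients 0, WL 0, RMS |c| and are
    logged.
    """
    if segs.n_samples <= 2 * p:
        raise ValueError("windows must be longer than 2p samples")
    n_inst, n_ch = segs.n_trials, segs.n_channels
    width = p + 2
    values = np.empty((n_inst, n_ch * width))
    n_degenerate = 0
    for ci in range(n_ch):
        col = ci * width
        for ii in range(n_inst):
            x = segs.data[ii, ci]
            if np.ptp(x) == 0:
                n_degenerate += 1
                values[ii, col:col + p] = 0.0
                values[ii, col + p] = abs(x[0])
                values[ii, col + p + 1] = 0.0
                continue
            values[ii, col:col + p] = burg(x, p)
            values[ii, col + p] = np.sqrt(np.mean(x * x))
            values[ii, col + p + 1] = np.abs(np.diff(x)).sum()
    if n_degenerate:
        logger.warning("%d constant channel windows: AR/WL set to 0, RMS=|c|",
                       n_degenerate)
    return FeatureMatrix(values, feature_names(segs.channel_labels, p),
                         segs.labels.copy(), groups=segs.parent_trial.copy())
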