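"""Comparison feature extractors: CSP, filter-bank CSP, and band power.

Multiclass CSP uses a one-vs-rest decomposition: for each class the
generalized eigenproblem between its mean (trace-normalized) trial
covariance and that of the remaining classes is solved, and the
eigenvectors at both spectral extremes are kept. With one maximal and one
minimal eigenvector per class this gives 3 x 2 = 6 spatial filters for the
three-class problem; applied per sub-band of the default three-band filter
bank it gives 18 features, and the log band-power route yields one feature
per channel (20 for the default montage).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from .containers import EpochSet, FeatureMatrix

logger = logging.getLogger(__name__)

#: Default filter-bank sub-bands (Hz).
DEFAULT_FILTER_BANK = [(7.0, 15.0), (15.0, 25.0), (25.0, 30.0)]

#: Default band for the band-power features (Hz).
DEFAULT_POWER_BAND = (8.0, 24.0)


@dataclass
class FilterBankSpec:
    """Ordered list of (lo, hi) band edges in Hz."""

    bands: list[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_FILTER_BANK))

    def __post_init__(self) -> None:
        for lo, hi in self.bands:
            if lo >= hi:
                raise ValueError("band edges must satisfy lo < hi")


@dataclass
class SpatialFilters:
    """CSP spatial filters with their variance-ratio eigenvalues.

    ``class_tags`` records, per filter, which one-vs-rest problem it came
    from and whether it sits at the max or min end of the spectrum.
    """

    filters: np.ndarray          # (n_filters, n_channels)
    eigenvalues: np.ndarray      # variance ratios in (0, 1)
    class_tags: list[tuple[str, str]]
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, float)
        self.eigenvalues = np.asarray(self.eigenvalues, float)
        if not np.all(np.isfinite(self.filters)):
            raise ValueError("filters must be finite")
        if len(self.class_tags) != self.filters.shape[0]:
            raise ValueError("one class tag per filter required")

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]


def _normalized_covariances(data: np.ndarray) -> np.ndarray:
    """Per-trial spatial covariance, each normalized by its trace."""
    covs = np.einsum("tcs,tds->tcd", data, data)
    traces = np.trace(covs, axis1=1, axis2=2)
    return covs / traces[:, None, None]


def fit_csp(epochs: EpochSet, n_per_class: int = 2) -> SpatialFilters:
    """Fit one-vs-rest CSP filters on a (multi)class epoch set.

    ``n_per_class`` eigenvectors are kept per class, split evenly between
    the largest and smallest generalized eigenvalues, so it must be even.
    Ill-conditioned composite covariances receive a small diagonal
    shrinkage (1e-6 of the mean diagonal) before the eigensolve.
    """
    classes = sorted(set(epochs.labels))
    if len(classes) < 2:
        raise ValueError("CSP needs at least 2 classes")
    if n_per_class < 2 or n_per_class % 2:
        raise ValueError("n_per_class must be a positive even count")
    for c in classes:
        if np.sum(epochs.labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 trials")
    covs = _normalized_covariances(epochs.data)
    n_ch = epochs.n_channels
    half = n_per_class // 2
    filters, eigvals, tags = [], [], []
    for c in classes:
        mask = epochs.labels == c
        ck = covs[mask].mean(axis=0)
        cr = covs[~mask].mean(axis=0)
        comp = ck + cr
        if np.linalg.cond(comp) > 1e10:
            logger.warning("ill-conditioned composite covariance for %r: "
                           "applying diagonal shrinkage", c)
            comp = comp + 1e-6 * np.trace(comp) / n_ch * np.eye(n_ch)
        w, v = linalg.eigh(ck, comp)  # ascending eigenvalues in (0, 1)
        for j in range(half):
            filters.append(v[:, -(j + 1)])
            eigvals.append(w[-(j + 1)])
            tags.append((c, "max"))
        for j in range(half):
            filters.append(v[:, j])
            eigvals.append(w[j])
            tags.append((c, "min"))
    return SpatialFilters(np.array(filters), np.array(eigvals), tags,
                          list(epochs.channel_labels))


def apply_csp(filters: SpatialFilters, epochs: EpochSet) -> FeatureMatrix:
    """Log normalized-variance features of the spatially filtered epochs.

    Per epoch, each filter's output variance is divided by the summed
    variance over the filter set (so an overall gain cancels), then logged.
    """
    if epochs.n_channels != filters.filters.shape[1]:
        raise ValueError("channel count mismatch between filters and epochs")
    projected = np.einsum("fc,tcs->tfs", filters.filters, epochs.data)
    var = projected.var(axis=2)
    var /= var.sum(axis=1, keepdims=True)
    names = [f"CSP{i + 1}[{c}/{ext}]"
             for i, (c, ext) in enumerate(filters.class_tags)]
    return FeatureMatrix(np.log(var), names, epochs.labels.copy(),
                         groups=np.arange(epochs.n_trials))


def _bandpass_epochs(epochs: EpochSet, lo: float, hi: float) -> EpochSet:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=epochs.fs,
                        output="sos")
    data = signal.sosfiltfilt(sos, epochs.data, axis=2)
    return EpochSet(data, epochs.fs, epochs.labels.copy(), epochs.window,
                    list(epochs.channel_labels))


def extract_fbcsp(epochs_raw: EpochSet, spec: FilterBankSpec | None = None,
                  n_per_class: int = 2) -> FeatureMatrix:
    """Filter-bank CSP: per sub-band band-pass, CSP fit+apply, concatenate.

    With the default three-band spec and 2 filters per class this gives
    3 bands x 6 = 18 columns.
    """
    spec = spec or FilterBankSpec()
    blocks, names = [], []
    for lo, hi in spec.bands:
        band_epochs = _bandpass_epochs(epochs_raw, lo, hi)
        fm = apply_csp(fit_csp(band_epochs, n_per_class), band_epochs)
        blocks.append(fm.values)
        names.extend(f"{lo:g}-{hi:g}Hz/{n}" for n in fm.feature_names)
    return FeatureMatrix(np.hstack(blocks), names, epochs_raw.labels.copy(),
                         groups=np.arange(epochs_raw.n_trials))


def extract_bandpower(epochs: EpochSet,
                      band: tuple[float, float] = DEFAULT_POWER_BAND
                      ) -> FeatureMatrix:
    """Log variance of each band-filtered channel: one column per channel."""
    lo, hi = band
    if not 0 < lo < hi < epochs.fs / 2:
        raise ValueError("band must lie inside (0, fs/2)")
    filtered = _bandpass_epochs(epochs, lo, hi)
    power = filtered.data.var(axis=2)
    names = [f"{ch}/BP" for ch in epochs.channel_labels]
    return FeatureMatrix(np.log(power), names, epochs.labels.copy(),
                         groups=np.arange(epochs.n_trials))
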