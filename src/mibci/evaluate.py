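"""Discriminability maps, confusion matrices, and method comparison.

The discriminability statistic is the BCI-standard r-squared: the squared
Pearson correlation between a feature and the 0/1 indicator of a two-task
contrast (equivalently the squared point-biserial correlation). Mapping it
over every (electrode, feature) column locates the scalp regions that
separate a task pair.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CVReport
from .containers import FeatureMatrix

logger = logging.getLogger(__name__)


def r_squared(values: np.ndarray, labels: np.ndarray) -> float:
    """Squared Pearson correlation with the binary class indicator.

    Requires both classes present with at least 2 instances each. A
    zero-variance feature returns 0 with a warning.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("labels must contain exactly 2 classes")
    y = (labels == classes[1]).astype(float)
    if min(y.sum(), len(y) - y.sum()) < 2:
        raise ValueError("need at least 2 instances per class")
    if values.std() == 0:
        logger.warning("zero-variance feature: r-squared set to 0")
        return 0.0
    r = np.corrcoef(values, y)[0, 1]
    return float(r * r)


def _r2_columns(X: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Vectorized r-squared of every column against a 0/1 indicator."""
    Xc = X - X.mean(axis=0)
    yc = y01 - y01.mean()
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    sy = np.sqrt((yc * yc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.where(sx == 0, 0.0, r)
    return r * r


@dataclass
class DiscriminabilityMap:
    """Per-(electrode, feature) r-squared table for one task pair.

    ``table`` columns: electrode, feature, r2. ``max_r2`` is the pooled
    maximum over all entries; ``per_feature_max`` the maximum within each
    feature type (AR/RMS/WL/...), since a headline figure may be quoted
    either way.
    """

    pair: tuple[str, str]
    table: pd.DataFrame

    @property
    def max_r2(self) -> float:
        return float(self.table["r2"].max())

    @property
    def argmax(self) -> tuple[str, str]:
        row = self.table.loc[self.table["r2"].idxmax()]
        return str(row["electrode"]), str(row["feature"])

    @property
    def per_feature_max(self) -> dict[str, float]:
        return self.table.groupby("feature")["r2"].max().to_dict()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _split_feature_name(name: str) -> tuple[str, str]:
    """'C3/RMS' -> ('C3', 'RMS'); names without '/' map to electrode ''. """
    if "/" in name:
        el, feat = name.split("/", 1)
        return el, feat
    return "", name


def max_r2_map(features: FeatureMatrix,
               pair: tuple[str, str]) -> DiscriminabilityMap:
    """r-squared of every feature column restricted to a task pair."""
    a, b = pair
    present = set(features.labels)
    if a not in present or b not in present:
        raise ValueError(f"pair {pair} not present in labels")
    mask = (features.labels == a) | (features.labels == b)
    y01 = (features.labels[mask] == b).astype(float)
    r2 = _r2_columns(features.values[mask], y01)
    rows = []
    for name, v in zip(features.feature_names, r2):
        el, feat = _split_feature_name(name)
        rows.append({"electrode": el, "feature": feat, "r2": float(v)})
    return DiscriminabilityMap((a, b), pd.DataFrame(rows))


def permutation_null_max_r2(features: FeatureMatrix, pair: tuple[str, str],
                            n_perm: int = 200, seed: int = 0) -> np.ndarray:
    """Null distribution of the pooled max r-squared under label shuffling."""
    a, b = pair
    mask = (features.labels == a) | (features.labels == b)
    X = features.values[mask]
    y01 = (features.labels[mask] == b).astype(float)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _r2_columns(X, rng.permutation(y01)).max()
    return null


@dataclass
class ConfusionMatrix:
    """Count and row-normalized confusion matrix over a fixed class list."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.classes),) * 2:
            raise ValueError("counts must be square over classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def rates(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rates, index=self.classes, columns=self.classes)


def confusion(preds: np.ndarray, labels: np.ndarray,
              classes: list[str] | None = None) -> ConfusionMatrix:
    """Build a confusion matrix from predictions and ground truth."""
    preds = np.asarray(preds, object)
    labels = np.asarray(labels, object)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must have equal length")
    if classes is None:
        classes = sorted(set(labels) | set(preds))
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, t in zip(preds, labels):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(list(classes), counts)


@dataclass
class MethodComparison:
    """Cross-method accuracy comparison with paired bootstrap intervals."""

    summary: pd.DataFrame    # per method: mean, sd, min, max
    pairwise: pd.DataFrame   # per pair: mean difference and 95% CI


def compare_methods(reports: dict[str, CVReport], n_boot: int = 2000,
                    seed: int = 0) -> MethodComparison:
    """Summarize named CV reports and bootstrap their paired differences.

    All reports must come from the same trials under the same CV scheme
    (checked via the fold-accuracy array shapes; feature methods may still
    differ in instances per trial, e.g. windowed vs per-epoch features);
    differences are paired per fold and resampled ``n_boot`` times for
    95% CIs.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    names = list(reports)
    ref = reports[names[0]]
    for n in names[1:]:
        if reports[n].fold_accuracies.shape != ref.fold_accuracies.shape:
            raise ValueError("reports cover mismatched instance sets")
    rows = []
    for n in names:
        acc = reports[n].fold_accuracies
        rows.append({"method": n, "mean": acc.mean(), "sd": acc.std(ddof=1),
                     "min": acc.min(), "max": acc.max()})
    summary = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    prows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = (reports[names[i]].fold_accuracies.ravel()
                 - reports[names[j]].fold_accuracies.ravel())
            idx = rng.integers(0, len(d), size=(n_boot, len(d)))
            boot = d[idx].mean(axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
            prows.append({"a": names[i], "b": names[j],
                          "mean_diff": float(d.mean()),
                          "ci_lo": float(lo), "ci_hi": float(hi)})
    return MethodComparison(summary, pd.DataFrame(prows))
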