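"""One-vs-one RBF-SVM classification with grid search and repeated CV.

The three-class problem is decomposed into n(n-1)/2 = 3 binary soft-margin
SVMs with a Gaussian (RBF) kernel; prediction uses max-wins voting, with
ties broken by the largest summed signed pairwise decision value and then
by the lowest class index. Hyper-parameters (penalty c, kernel width
gamma) are selected by grid search over the open intervals (0, 100] and
(0, 3] via inner cross-validation on the training partition only.

Evaluation is 10 repetitions of stratified 10-fold cross-validation with
re-randomized fold assignment. Feature standardization and any
data-dependent extractor (CSP) are refit inside each outer training set,
so no test-fold statistics ever leak into training. Analysis windows cut
from the same trial are kept on the same side of every fold by default
(trial-level grouping), since sibling windows are strongly autocorrelated.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .containers import EpochSet, FeatureMatrix

logger = logging.getLogger(__name__)

#: Default search grids over the intervals (0, 100] for c and (0, 3] for
#: gamma. The gamma
#: grid extends below 0.1 because with ~120 standardized features the
#: squared distances between instances are large (of order the feature
#: count), putting the useful kernel widths in the 0.01-0.1 range.
DEFAULT_C_GRID = tuple(range(5, 101, 5))
DEFAULT_GAMMA_GRID = ((0.01, 0.02, 0.05)
                      + tuple(round(0.1 * k, 1) for k in range(1, 31)))


@dataclass(frozen=True)
class SVMHyper:
    """RBF-SVM hyper-parameters: penalty ``c`` and kernel width ``gamma``."""

    c: float
    gamma: float

    def __post_init__(self) -> None:
        if self.c <= 0 or self.gamma <= 0:
            raise ValueError("c and gamma must be positive")


def rbf_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """Gaussian kernel exp(-gamma * ||u - v||^2); symmetric, in (0, 1]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    d = u - v
    return float(np.exp(-gamma * (d @ d)))


class FeatureScaler:
    """Per-feature standardization fit on training rows only.

    Constant columns pass through unscaled (with a logged warning), since
    their z-score is undefined.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        constant = np.ptp(X, axis=0) == 0
        if constant.any():
            logger.warning("%d constant feature columns pass through "
                           "unscaled", int(constant.sum()))
            self.mean_ = np.where(constant, 0.0, self.mean_)
            sd = np.where(constant, 1.0, sd)
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler has not been fitted")
        return (np.asarray(X, float) - self.mean_) / self.scale_


@dataclass
class OVOModel:
    """Trained one-vs-one ensemble: one binary RBF-SVM per class pair.

    Tie rule for max-wins voting: among the classes with the most votes,
    pick the one with the largest sum of signed pairwise decision values;
    remaining ties go to the lowest index in ``class_list``.
    """

    class_list: list[str]
    pairs: list[tuple[int, int]]
    binary_models: list[SVC]
    scaler: FeatureScaler | None
    hyper: SVMHyper

    def parameter_digest(self) -> str:
        """SHA-256 over all learned parameters (for reproducibility checks)."""
        h = hashlib.sha256()
        for m in self.binary_models:
            for arr in (m.support_, m.dual_coef_, m.intercept_,
                        m.support_vectors_):
                h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


def train_ovo(features: FeatureMatrix, hyper: SVMHyper,
              standardize: bool = True) -> OVOModel:
    """Train n(n-1)/2 pairwise soft-margin RBF-SVMs.

    Each binary model sees only the rows of its two classes. Features are
    standardized with statistics computed from the given (training) rows.
    """
    classes = sorted(set(features.labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(features.labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 instances")
    X = features.values
    scaler = None
    if standardize:
        scaler = FeatureScaler().fit(X)
        X = scaler.transform(X)
    pairs, models = [], []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            mask = (features.labels == classes[i]) | (features.labels == classes[j])
            y = (features.labels[mask] == classes[j]).astype(int)
            svc = SVC(C=hyper.c, gamma=hyper.gamma, kernel="rbf", tol=1e-3)
            svc.fit(X[mask], y)
            pairs.append((i, j))
            models.append(svc)
    return OVOModel(classes, pairs, models, scaler, hyper)


def predict(model: OVOModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Max-wins voting over the pairwise classifiers (see OVOModel tie rule)."""
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if model.scaler is not None:
        if X.shape[1] != len(model.scaler.mean_):
            raise ValueError("feature count does not match the trained scaler")
        X = model.scaler.transform(X)
    n = X.shape[0]
    k = len(model.class_list)
    votes = np.zeros((n, k))
    decision_sum = np.zeros((n, k))
    for (i, j), svc in zip(model.pairs, model.binary_models):
        # decision value > 0 favours class j (label 1 at training time)
        d = svc.decision_function(X)
        win_j = d > 0
        votes[win_j, j] += 1
        votes[~win_j, i] += 1
        decision_sum[:, j] += d
        decision_sum[:, i] -= d
    out = np.empty(n, dtype=object)
    for r in range(n):
        top = np.flatnonzero(votes[r] == votes[r].max())
        if len(top) > 1:
            top = top[decision_sum[r, top] == decision_sum[r, top].max()]
        out[r] = model.class_list[top[0]]
    return out


def _accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean(pred == truth))


def _make_folds(labels: np.ndarray, groups: np.ndarray | None, n_splits: int,
                seed: int):
    y = np.asarray(labels, object).astype(str)
    if groups is None:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros(len(y)), y))
    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y, groups))


def grid_search(features: FeatureMatrix, c_grid=DEFAULT_C_GRID,
                gamma_grid=DEFAULT_GAMMA_GRID, inner_folds: int = 10,
                seed: int = 0, groups: np.ndarray | None = None,
                standardize: bool = True):
    """Select (c, gamma) maximizing mean inner-CV accuracy.

    Returns the best :class:`SVMHyper` together with the full score surface
    (array of shape ``(len(c_grid), len(gamma_grid))``, in %). Ties resolve
    to the first grid cell in row-major order, so results are deterministic
    for a given seed.
    """
    c_grid = list(c_grid)
    gamma_grid = list(gamma_grid)
    if not c_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    folds = _make_folds(features.labels, groups, inner_folds, seed)
    surface = np.zeros((len(c_grid), len(gamma_grid)))
    for tr, te in folds:
        train_fm = FeatureMatrix(features.values[tr], features.feature_names,
                                 features.labels[tr])
        for a, c in enumerate(c_grid):
            for b, g in enumerate(gamma_grid):
                model = train_ovo(train_fm, SVMHyper(c, g),
                                  standardize=standardize)
                surface[a, b] += _accuracy(predict(model, features.values[te]),
                                           features.labels[te])
    surface *= 100.0 / len(folds)
    a, b = np.unravel_index(np.argmax(surface), surface.shape)
    return SVMHyper(c_grid[a], gamma_grid[b]), surface


@dataclass
class CVReport:
    """Repeated cross-validation result.

    ``fold_accuracies`` has shape (repetitions, folds), in %. The confusion
    matrix accumulates counts over all repetitions.
    """

    fold_accuracies: np.ndarray
    class_list: list[str]
    confusion_counts: np.ndarray
    selected_hyper: list[list[dict]]
    seed: int
    n_instances: int

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        diag = np.diag(self.confusion_counts)
        totals = self.confusion_counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(totals > 0, diag / totals, np.nan)
        return dict(zip(self.class_list, (float(r) for r in rates)))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fold_accuracies": self.fold_accuracies.tolist(),
            "class_list": self.class_list,
            "confusion_counts": self.confusion_counts.tolist(),
            "selected_hyper": self.selected_hyper,
            "seed": self.seed,
            "n_instances": self.n_instances,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CVReport":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["fold_accuracies"]), d["class_list"],
                   np.array(d["confusion_counts"]), d["selected_hyper"],
                   d["seed"], d["n_instances"])


class PrecomputedExtractor:
    """Fold extractor for features that do not depend on the training set."""

    def __init__(self, fm: FeatureMatrix):
        self.fm = fm
        self.labels = fm.labels
        self.groups = fm.groups
        self.feature_names = fm.feature_names

    def features(self, train_idx, test_idx):
        return self.fm.values[train_idx], self.fm.values[test_idx]


class CSPRefitExtractor:
    """Refits a CSP-family extractor on the training trials of each fold.

    ``method`` is ``"csp"`` or ``"fbcsp"``; the extractor is re-estimated
    from the training epochs only, preventing spatial-filter leakage.
    """

    def __init__(self, epochs: EpochSet, method: str = "csp",
                 n_per_class: int = 2, filter_bank=None):
        from .features_baseline import FilterBankSpec
        if method not in ("csp", "fbcsp"):
            raise ValueError("method must be 'csp' or 'fbcsp'")
        self.epochs = epochs
        self.method = method
        self.n_per_class = n_per_class
        self.filter_bank = filter_bank or FilterBankSpec()
        self.labels = epochs.labels
        self.groups = np.arange(epochs.n_trials)

    def _subset(self, idx) -> EpochSet:
        return EpochSet(self.epochs.data[idx], self.epochs.fs,
                        self.epochs.labels[idx], self.epochs.window,
                        list(self.epochs.channel_labels))

    def features(self, train_idx, test_idx):
        from .features_baseline import apply_csp, extract_fbcsp, fit_csp
        train = self._subset(train_idx)
        test = self._subset(test_idx)
        if self.method == "csp":
            filters = fit_csp(train, self.n_per_class)
            return (apply_csp(filters, train).values,
                    apply_csp(filters, test).values)
        # fbcsp: fit per-band CSP on train only, then apply to both; done by
        # concatenating train and test through per-band filters
        from .features_baseline import _bandpass_epochs
        tr_blocks, te_blocks = [], []
        for lo, hi in self.filter_bank.bands:
            tr_band = _bandpass_epochs(train, lo, hi)
            te_band = _bandpass_epochs(test, lo, hi)
            filters = fit_csp(tr_band, self.n_per_class)
            tr_blocks.append(apply_csp(filters, tr_band).values)
            te_blocks.append(apply_csp(filters, te_band).values)
        return np.hstack(tr_blocks), np.hstack(te_blocks)


def cross_validate_10x10(extractor, c_grid=DEFAULT_C_GRID,
                         gamma_grid=DEFAULT_GAMMA_GRID, reps: int = 10,
                         folds: int = 10, inner_folds: int = 10,
                         seed: int = 0, standardize: bool = True,
                         group_trials: bool = True) -> CVReport:
    """Repeated stratified k-fold evaluation with nested grid search.

    ``extractor`` is a :class:`PrecomputedExtractor`, a
    :class:`CSPRefitExtractor`, or a plain :class:`FeatureMatrix` (wrapped
    automatically). Within every outer training set the extractor is
    refit, the scaler fit, the grid searched by inner CV, and the final
    model trained; the held-out fold is scored once. Identical seeds give
    identical reports.
    """
    if isinstance(extractor, FeatureMatrix):
        extractor = PrecomputedExtractor(extractor)
    labels = np.asarray(extractor.labels, object)
    groups = extractor.groups if group_trials else None
    classes = sorted(set(labels))
    for c in classes:
        n_c = int(np.sum(labels == c))
        if n_c < folds:
            raise ValueError(f"class {c!r} has {n_c} instances; "
                             f"need at least {folds}")
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                 for s in ss.spawn(reps)]
    k = len(classes)
    cls_index = {c: i for i, c in enumerate(classes)}
    fold_acc = np.zeros((reps, folds))
    confusion = np.zeros((k, k), dtype=np.int64)
    selected: list[list[dict]] = []
    feature_names = getattr(extractor, "feature_names", None)
    for r, rs in enumerate(rep_seeds):
        rep_sel: list[dict] = []
        for f, (tr, te) in enumerate(_make_folds(labels, groups, folds, rs)):
            Xtr, Xte = extractor.features(tr, te)
            names = feature_names or [f"f{i}" for i in range(Xtr.shape[1])]
            train_fm = FeatureMatrix(Xtr, names, labels[tr],
                                     groups=None if groups is None else groups[tr])
            hyper, _ = grid_search(train_fm, c_grid, gamma_grid,
                                   inner_folds=inner_folds, seed=rs,
                                   groups=None if groups is None else groups[tr],
                                   standardize=standardize)
            model = train_ovo(train_fm, hyper, standardize=standardize)
            pred = predict(model, Xte)
            fold_acc[r, f] = 100.0 * _accuracy(pred, labels[te])
            rep_sel.append({"c": hyper.c, "gamma": hyper.gamma})
            for p, t in zip(pred, labels[te]):
                confusion[cls_index[t], cls_index[p]] += 1
        selected.append(rep_sel)
    return CVReport(fold_acc, classes, confusion, selected, seed, len(labels))
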