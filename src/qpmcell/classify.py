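"""Linear soft-margin SVM training and cross-validated evaluation.

The classifier is a linear C-SVC: minimize ½‖w‖² + C·Σ hinge losses.
With 250 sample pairs and up to 1296 HOG elements the problem is
under-determined, which is exactly the regime where the linear kernel is
the appropriate choice.  The reported decision value is the signed
Euclidean distance to the hyperplane,

    d(x) = (w·x + b) / ‖w‖,

positive ⇒ the cell is classified as a white blood cell (WBC, the
positive class).  Model selection sweeps the cost C over integer powers
of two (2⁻¹ … 2⁸ by default) maximizing the mean 5-fold cross-validated
AUC; features enter the SVM unstandardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from qpmcell.features import FeatureVector

POSITIVE = "WBC"   # positive class label (decision value > 0)
NEGATIVE = "CL"

DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-1, 9))


@dataclass
class TrainedClassifier:
    """A trained linear SVM: weights, bias and provenance metadata."""

    w: np.ndarray
    b: float
    C: float
    feature_kind: str = "hog"
    normalization_mode: str = "OPL_PL"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64).ravel()
        if self.norm_w <= 0:
            raise ValueError("trained classifier must have ‖w‖ > 0")

    @property
    def norm_w(self) -> float:
        return float(np.linalg.norm(self.w))


@dataclass
class Evaluation:
    """ROC/DET curves, AUC, and zero-threshold operating-point metrics."""

    roc_points: np.ndarray       # columns: (1 - specificity, sensitivity)
    det_points: np.ndarray       # columns: (1 - specificity, 1 - sensitivity)
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class CVResult:
    """C grid-search result: per-C mean CV AUC and the winning model."""

    grid: list[tuple[float, float]]
    best_C: float
    seed: int
    model: TrainedClassifier | None = None


def _as_matrix(X: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return np.asarray(X, dtype=np.float64)
    return np.stack([fv.values for fv in X]).astype(np.float64)


def _as_pm1(y: Iterable) -> np.ndarray:
    """Map labels to ±1 with the WBC/positive convention."""
    out = []
    for lab in y:
        if lab in (1, +1, POSITIVE, "positive", True):
            out.append(1)
        elif lab in (-1, 0, NEGATIVE, "negative", False):
            out.append(-1)
        else:
            raise ValueError(f"unrecognized class label: {lab!r}")
    return np.array(out)


def train_svm(
    X: Sequence[FeatureVector] | np.ndarray,
    y: Iterable,
    C: float = 1.0,
    feature_kind: str = "hog",
    normalization_mode: str = "OPL_PL",
) -> TrainedClassifier:
    """Fit a linear C-SVC and return its primal (w, b).

    The optimum of ½‖w‖² + C·Σξ is what matters, not the solver; the
    libsvm SMO implementation is used underneath.
    """
    Xm, ym = _as_matrix(X), _as_pm1(y)
    if len(np.unique(ym)) < 2:
        raise ValueError("training requires both classes to be present")
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xm, ym)
    return TrainedClassifier(
        w=clf.coef_[0],
        b=float(clf.intercept_[0]),
        C=C,
        feature_kind=feature_kind,
        normalization_mode=normalization_mode,
    )


def decision_value(
    clf: TrainedClassifier, x: FeatureVector | np.ndarray
) -> float:
    """Signed distance to the hyperplane, d = (w·x + b)/‖w‖; d > 0 ⇒ WBC."""
    xv = x.values if isinstance(x, FeatureVector) else np.asarray(x, float).ravel()
    if xv.size != clf.w.size:
        raise ValueError("feature dimension does not match the classifier")
    return float((clf.w @ xv + clf.b) / clf.norm_w)


def decision_values(clf: TrainedClassifier, X) -> np.ndarray:
    Xm = _as_matrix(X)
    return (Xm @ clf.w + clf.b) / clf.norm_w


def cross_validated_decisions(
    X, y, C: float = 1.0, k: int = 5, seed: int = 0
) -> np.ndarray:
    """Out-of-fold decision values under stratified k-fold CV.

    Each sample's decision value comes from the one fold model that did
    not see it during training; deterministic given the seed.
    """
    Xm, ym = _as_matrix(X), _as_pm1(y)
    for cls in (-1, 1):
        if np.sum(ym == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    d = np.empty(len(ym))
    for train_idx, test_idx in skf.split(Xm, ym):
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xm[train_idx], ym[train_idx])
        w, b = clf.coef_[0], float(clf.intercept_[0])
        d[test_idx] = (Xm[test_idx] @ w + b) / np.linalg.norm(w)
    return d


def _fold_mean_auc(Xm, ym, C, k, seed) -> float:
    """Mean of per-fold AUCs under stratified k-fold CV."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in skf.split(Xm, ym):
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xm[train_idx], ym[train_idx])
        d = clf.decision_function(Xm[test_idx])
        aucs.append(evaluate(d, ym[test_idx]).auc)
    return float(np.mean(aucs))


def grid_search_C(
    X, y,
    grid: Sequence[float] = DEFAULT_C_GRID,
    k: int = 5,
    seed: int = 0,
    feature_kind: str = "hog",
    normalization_mode: str = "OPL_PL",
) -> CVResult:
    """Sweep C over the grid maximizing mean CV AUC; ties → smallest C.

    The final model is retrained on all data at the winning C.
    """
    if len(grid) == 0:
        raise ValueError("C grid must be nonempty")
    Xm, ym = _as_matrix(X), _as_pm1(y)
    results = [(float(C), _fold_mean_auc(Xm, ym, C, k, seed)) for C in sorted(grid)]
    best_auc = max(a for _, a in results)
    best_C = min(C for C, a in results if a == best_auc)
    model = train_svm(Xm, ym, C=best_C, feature_kind=feature_kind,
                      normalization_mode=normalization_mode)
    model.meta["cv_auc"] = best_auc
    return CVResult(grid=results, best_C=best_C, seed=seed, model=model)


def evaluate(decisions, labels) -> Evaluation:
    """ROC/DET curves and operating-point metrics from decision values.

    The ROC sweeps the threshold over all distinct decision values; AUC
    is the trapezoidal area (equal to the Mann–Whitney statistic with
    ties counted ½).  Sensitivity, specificity and accuracy are computed
    at the d = 0 threshold (d > 0 ⇒ positive/WBC).
    """
    d = np.asarray(decisions, dtype=np.float64)
    ym = _as_pm1(labels)
    if len(np.unique(ym)) < 2:
        raise ValueError("evaluation requires both classes")
    fpr, tpr, _ = _roc_curve(ym, d, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    roc = np.column_stack([fpr, tpr])
    det = np.column_stack([fpr, 1.0 - tpr])
    pos, neg = ym == 1, ym == -1
    sens = float(np.mean(d[pos] > 0))
    spec = float(np.mean(d[neg] <= 0))
    acc = float((np.sum(d[pos] > 0) + np.sum(d[neg] <= 0)) / len(ym))
    return Evaluation(roc_points=roc, det_points=det, auc=auc,
                      sensitivity=sens, specificity=spec, accuracy=acc)


def learning_curve(
    X, y, sizes: Sequence[int], C: float = 16.0, k: int = 5, seed: int = 0
) -> list[tuple[int, float]]:
    """CV AUC versus training-set size at fixed C (default 16).

    For each n, n positive and n negative samples are drawn (seeded,
    without replacement) and the out-of-fold AUC is computed.
    """
    Xm, ym = _as_matrix(X), _as_pm1(y)
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.flatnonzero(ym == 1), np.flatnonzero(ym == -1)
    out = []
    for n in sizes:
        if n > min(len(pos_idx), len(neg_idx)):
            raise ValueError(f"requested {n} pairs but only "
                             f"{min(len(pos_idx), len(neg_idx))} available")
        sel = np.concatenate([
            rng.choice(pos_idx, size=n, replace=False),
            rng.choice(neg_idx, size=n, replace=False),
        ])
        d = cross_validated_decisions(Xm[sel], ym[sel], C=C, k=k, seed=seed)
        out.append((int(n), evaluate(d, ym[sel]).auc))
    return out


def phantom_decision_curve(
    clf: TrainedClassifier,
    phantom_series,
    mode: str | None = None,
    heights: Sequence[float] | None = None,
) -> list[tuple[float, float]]:
    """Decision value of each phantom in a bump-height series.

    Each phantom runs through the same preprocessing and feature
    extraction the classifier was trained with; the result is the
    interpretability curve of decision value versus bump height.
    """
    from qpmcell.features import compute_hog, stat_features
    from qpmcell.normalization import preprocess_cell

    mode = mode or clf.normalization_mode
    if mode != clf.normalization_mode:
        raise ValueError(
            f"classifier was trained on {clf.normalization_mode}, got {mode}")
    out = []
    for i, cell in enumerate(phantom_series):
        ncell = preprocess_cell(cell, mode=mode)
        if clf.feature_kind == "hog":
            fv = compute_hog(ncell)
        elif clf.feature_kind == "stats":
            fv = stat_features(ncell)
        else:
            raise ValueError(f"unknown feature kind {clf.feature_kind!r}")
        h = heights[i] if heights is not None else float(i)
        out.append((float(h), decision_value(clf, fv)))
    return out
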