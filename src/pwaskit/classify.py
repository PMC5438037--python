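"""Under-sampled random-forest pathway classifiers and evaluation metrics.

Class imbalance is handled by randomly down-sampling the majority class to
the minority count before fitting.  The forest is a standard bagged
ensemble (scikit-learn) with parameters pinned explicitly — 500 trees,
``sqrt(p)`` candidate features per split, unlimited depth — because library
defaults drift between versions.  Missing genotypes are imputed to the
training-set per-SNP mode before fitting and at prediction time.

Evaluation assigns class labels at predicted probability 0.5, computes AUC
as the mid-rank Mann-Whitney statistic of the predicted probabilities, and
reports the confusion-matrix odds ratio ``(tp*tn)/(fp*fn)`` with the
Haldane-Anscombe 0.5 correction added to all four cells iff any cell is
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .config import ForestConfig
from .errors import ClassBalanceError, TooFewFeaturesError

__all__ = [
    "undersample_majority",
    "train_forest",
    "evaluate",
    "metrics_from_scores",
    "midrank_auc",
    "ConfusionMetrics",
    "FittedForest",
]

_MISSING = -1
_FEATURE_RULE = {"sqrt": "sqrt", "log2": "log2", "all": None}


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts plus the five pathway performance metrics."""

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    odds_ratio: float

    @classmethod
    def from_counts(cls, tp: int, fn: int, fp: int, tn: int, auc: float) -> "ConfusionMetrics":
        total = tp + fn + fp + tn
        if tp + fn == 0 or tn + fp == 0:
            raise ClassBalanceError("evaluation set must contain both classes")
        a, b, c, d = float(tp), float(fn), float(fp), float(tn)
        if min(a, b, c, d) == 0:  # Haldane-Anscombe correction
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return cls(
            tp=tp,
            fn=fn,
            fp=fp,
            tn=tn,
            sensitivity=tp / (tp + fn),
            specificity=tn / (tn + fp),
            accuracy=(tp + tn) / total,
            auc=float(auc),
            odds_ratio=(a * d) / (c * b),
        )


def undersample_majority(labels: np.ndarray, rng: np.random.Generator | int) -> np.ndarray:
    """Indices retaining all minority-class samples and a random
    without-replacement subset of the majority class of equal size."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    y = np.asarray(labels)
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if len(cases) == 0 or len(controls) == 0:
        raise ClassBalanceError("under-sampling needs both classes")
    if len(cases) > len(controls):
        cases = np.sort(rng.choice(cases, size=len(controls), replace=False))
    elif len(controls) > len(cases):
        controls = np.sort(rng.choice(controls, size=len(cases), replace=False))
    return np.sort(np.concatenate([cases, controls]))


@dataclass
class FittedForest:
    """A fitted forest plus the training-set imputation modes."""

    model: RandomForestClassifier
    impute_modes: np.ndarray
    n_features: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-sample case probability."""
        X = self._impute(X)
        case_col = int(np.flatnonzero(self.model.classes_ == 1)[0])
        return self.model.predict_proba(X)[:, case_col]

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32).copy()
        for j in range(X.shape[1]):
            col = X[:, j]
            col[col == _MISSING] = self.impute_modes[j]
        return X


def _column_modes(X: np.ndarray) -> np.ndarray:
    modes = np.empty(X.shape[1], dtype=np.float32)
    for j in range(X.shape[1]):
        col = X[:, j]
        col = col[col != _MISSING]
        if len(col) == 0:
            modes[j] = 0.0
        else:
            counts = np.bincount(col.astype(np.int64), minlength=3)
            modes[j] = float(np.argmax(counts))
    return modes


def train_forest(X: np.ndarray, y: np.ndarray, cfg: ForestConfig) -> FittedForest:
    """Fit the pathway random forest on selected-SNP genotypes.

    Raises :class:`TooFewFeaturesError` — the pathway-exclusion signal —
    when fewer than two features are supplied, mirroring the rule that a
    pathway whose consensus SNP set drops below two features cannot be
    modeled.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] < 2:
        raise TooFewFeaturesError(
            f"pathway model requires >= 2 features, got {0 if X.ndim != 2 else X.shape[1]}"
        )
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ClassBalanceError("training labels must contain both classes")
    modes = _column_modes(X)
    forest = FittedForest(
        RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_features=_FEATURE_RULE[cfg.features_per_split],
            random_state=cfg.seed,
            n_jobs=1,
        ),
        modes,
        X.shape[1],
    )
    forest.model.fit(forest._impute(X), y)
    return forest


def midrank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic with mid-ranks for ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ClassBalanceError("AUC needs both classes")
    ranks = rankdata(scores, method="average")
    r1 = float(ranks[y == 1].sum())
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def metrics_from_scores(scores: np.ndarray, y: np.ndarray) -> ConfusionMetrics:
    """Metrics from per-sample case probabilities against true labels.

    Cases are called at probability >= 0.5 (consistent with training on an
    under-sampled, balanced set).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ClassBalanceError("evaluation set must contain both classes")
    pred = (np.asarray(scores) >= 0.5).astype(np.int8)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    auc = midrank_auc(scores, y)
    return ConfusionMetrics.from_counts(tp, fn, fp, tn, auc)


def evaluate(forest: FittedForest, X_test: np.ndarray, y_test: np.ndarray) -> ConfusionMetrics:
    """Evaluate a fitted forest on a held-out set."""
    return metrics_from_scores(forest.predict_proba(X_test), y_test)
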