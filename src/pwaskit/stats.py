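"""Resampling association statistics for pathway classifiers.

For each pathway the discovery cohort is split 100 times (stratified 80/20)
into a selection set and a test set.  Each iteration runs the subsampled
mRmR consensus selection, under-samples the majority class, fits the random
forest on the selected SNPs, and evaluates it on the 20% test set, on the
independent validation cohort when one exists, and on label-permuted copies
of those same evaluation sets (same trained classifier, only the labels
shuffle).  The pathway p-value is a two-sided Welch t-test comparing the
100 real odds ratios with the 100 permuted ones; Benjamini-Hochberg
adjustment runs over the family of pathways that survive the two-feature
rule.  Variance explained is the Nagelkerke pseudo R-squared of a logistic
model of case status, by default on the out-of-sample classifier
probability.

Seeding: every stochastic stage derives its generator from
``SeedSequence(master_seed, spawn_key=(crc32(pathway_id), iteration,
stage))`` (see :mod:`pwaskit._rng`), so a fixed master seed reproduces the
full pipeline byte-for-byte and results do not depend on pathway execution
order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import Logit
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from ._rng import STAGE, derive_int_seed, derive_rng, path_key
from .classify import metrics_from_scores, train_forest, undersample_majority
from .config import ForestConfig, MrmrConfig
from .dataset import GenotypeDataset
from .errors import (
    ClassBalanceError,
    DataError,
    DegenerateInputError,
    TooFewFeaturesError,
)
from .pathways import PathwaySnpPool
from .selection import SelectionTrace, consensus_select

__all__ = [
    "stratified_split",
    "permute_labels",
    "pathway_pvalue",
    "bh_adjust",
    "metric_ci",
    "nagelkerke_r2",
    "NagelkerkeResult",
    "combined_r2",
    "run_pathway",
    "run_pwas",
    "PathwayResult",
    "results_frame",
]

METRIC_NAMES = ("sensitivity", "specificity", "auc", "accuracy", "odds_ratio")

_logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# resampling primitives
# ---------------------------------------------------------------------------

def stratified_split(
    labels: np.ndarray, fraction: float = 0.8, rng: np.random.Generator | int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split into (selection, test) index arrays.

    Each class contributes ``round-half-up(fraction * class size)`` samples
    to the selection side; the split is disjoint and exhaustive.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    y = np.asarray(labels)
    sel, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ClassBalanceError(f"class {cls} has fewer than 2 members")
        n_sel = int(np.floor(fraction * len(idx) + 0.5))
        perm = rng.permutation(idx)
        sel.append(perm[:n_sel])
        test.append(perm[n_sel:])
    if len(sel) < 2:
        raise ClassBalanceError("both classes required for a stratified split")
    return np.sort(np.concatenate(sel)), np.sort(np.concatenate(test))


def permute_labels(labels: np.ndarray, rng: np.random.Generator | int = 0) -> np.ndarray:
    """Uniformly random permutation of the label vector (class counts kept)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("labels must be nonempty")
    return rng.permutation(y)


def pathway_pvalue(real_ors: Sequence[float], perm_ors: Sequence[float]) -> float:
    """Two-sided Welch t-test between real and permuted odds-ratio samples."""
    a = np.asarray(real_ors, dtype=float)
    b = np.asarray(perm_ors, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("need >= 2 odds ratios per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 1.0
        raise DegenerateInputError("zero variance in both odds-ratio samples")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def metric_ci(
    values: Sequence[float], confidence: float = 0.95, method: str = "normal"
) -> tuple[float, float, float]:
    """(mean, lower, upper) interval for the mean over iterations.

    ``normal`` uses mean +/- z * sd/sqrt(n); ``percentile`` uses empirical
    quantiles of the iteration values.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise DegenerateInputError("need >= 2 values for a confidence interval")
    mean = float(v.mean())
    if method == "normal":
        z = sps.norm.ppf(0.5 + confidence / 2)
        half = float(z * v.std(ddof=1) / np.sqrt(len(v)))
        return mean, mean - half, mean + half
    if method == "percentile":
        alpha = (1 - confidence) / 2
        lo, hi = np.quantile(v, [alpha, 1 - alpha])
        return mean, float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


# ---------------------------------------------------------------------------
# Nagelkerke pseudo R-squared
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NagelkerkeResult:
    """Nagelkerke R² with its Cox-Snell base and convergence flags."""

    r2: float
    cox_snell: float
    separation: bool = False
    converged: bool = True


def nagelkerke_r2(y: np.ndarray, score: np.ndarray) -> NagelkerkeResult:
    """Nagelkerke pseudo R-squared of a logistic fit of ``y`` on ``score``.

    ``score`` may be one predictor (classifier probability) or a dosage
    matrix; in integer dosage input, ``-1`` entries are treated as missing
    genotypes and mode-imputed per column.  The Cox-Snell
    R-squared ``1 - (L0/L1)^(2/n)`` is rescaled by its maximum
    ``1 - L0^(2/n)`` and clipped to [0, 1].  Perfect separation is reported
    via ``separation=True`` with the upper-bound value 1.0.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ClassBalanceError("both classes required")
    raw = np.asarray(score)
    is_dosage = np.issubdtype(raw.dtype, np.integer)
    X = raw.astype(float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != len(y):
        raise ValueError("score and labels must have equal length")
    if not np.all(np.isfinite(X)):
        raise ValueError("scores must be finite")
    if is_dosage and (X == -1).any():
        # integer dosage matrix with missing codes: per-column mode imputation
        X = X.copy()
        for j in range(X.shape[1]):
            col = X[:, j]
            miss = col == -1
            if miss.any():
                vals = col[~miss].astype(np.int64)
                col[miss] = np.argmax(np.bincount(vals, minlength=3)) if len(vals) else 0.0
    n = len(y)
    p1 = y.mean()
    ll0 = n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1))
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    if np.ptp(X, axis=0).max() == 0:  # constant predictor(s): null model
        return NagelkerkeResult(0.0, 0.0)
    design = np.column_stack([np.ones(n), X])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = Logit(y, design).fit(disp=0, maxiter=100)
            ll1 = float(fit.llf)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            # separation or singular fit: likelihood tends to the saturated bound
            return NagelkerkeResult(1.0, float(denom), separation=True, converged=False)
    separation = any(
        issubclass(w.category, PerfectSeparationWarning) for w in caught
    )
    if not separation:
        converged = converged and not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
    cs = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    r2 = float(np.clip(cs / denom, 0.0, 1.0))
    if separation:
        r2 = 1.0
    return NagelkerkeResult(r2, float(np.clip(cs, 0.0, 1.0)), separation, converged)


def combined_r2(
    snp_sets: Iterable[Iterable[str]], ds: GenotypeDataset
) -> NagelkerkeResult:
    """Nagelkerke R² of the union of pathway SNP sets as a dosage model."""
    union: list[str] = []
    seen = set()
    for snps in snp_sets:
        for s in snps:
            if s not in seen:
                seen.add(s)
                union.append(s)
    if not union:
        raise DataError("combined R²: union of selected SNPs is empty")
    cols = ds.snp_indices(union)
    return nagelkerke_r2(ds.phenotypes, ds.genotypes[:, cols])


# ---------------------------------------------------------------------------
# per-pathway pipeline
# ---------------------------------------------------------------------------

@dataclass
class PathwayResult:
    """Point estimates, permutation p, and R² for one pathway."""

    pathway_id: str
    metrics: dict[str, tuple[float, float, float]]  # name -> (mean, lo, hi)
    p_raw: float
    nagelkerke_r2: float
    n_iterations: int
    excluded: bool = False
    n_failed_iterations: int = 0
    p_bh: float = float("nan")
    r2_separation_flagged: bool = False
    or_real: np.ndarray | None = field(default=None, repr=False)
    or_perm: np.ndarray | None = field(default=None, repr=False)
    iteration_metrics: pd.DataFrame | None = field(default=None, repr=False)


def run_pathway(
    pool: PathwaySnpPool,
    discovery: GenotypeDataset,
    validation: GenotypeDataset | None = None,
    *,
    mrmr: MrmrConfig | None = None,
    forest: ForestConfig | None = None,
    n_iterations: int = 100,
    split_fraction: float = 0.8,
    master_seed: int = 0,
) -> tuple[PathwayResult, SelectionTrace]:
    """Run the full resampling pipeline for one pathway.

    Point estimates, confidence intervals, the permutation p-value and the
    Nagelkerke R² use the validation cohort when one is supplied, else the
    20% test split (the fallback for cohorts without an independent
    validation set).  A pathway whose consensus SNP set holds fewer than two
    SNPs in any iteration is marked ``excluded`` (its selection trace is
    still completed).
    """
    mrmr = mrmr or MrmrConfig()
    forest = forest or ForestConfig()
    discovery.require_both_classes()
    pkey = path_key(pool.pathway_id)
    y = discovery.phenotypes

    pool_cols = discovery.snp_indices(pool.snp_ids) if pool.snp_ids else np.array([], dtype=int)
    X_pool = discovery.genotypes[:, pool_cols]
    if validation is not None:
        val_cols = validation.snp_indices(pool.snp_ids) if pool.snp_ids else np.array([], dtype=int)
        X_val_pool = validation.genotypes[:, val_cols]
        y_val = validation.phenotypes

    iters_sel: list[tuple[str, ...]] = []
    per_metric: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    or_perm: list[float] = []
    r2_vals: list[float] = []
    r2_sep = False
    excluded = False
    n_failed = 0
    log_rows: list[tuple] = []

    def log_metrics(it: int, dataset: str, m) -> None:
        log_rows.append(
            (pool.pathway_id, it, dataset, m.tp, m.fn, m.fp, m.tn,
             m.sensitivity, m.specificity, m.accuracy, m.auc, m.odds_ratio)
        )

    for it in range(n_iterations):
        _logger.debug(
            "stage=iteration pathway=%s iteration=%d master_seed=%d",
            pool.pathway_id, it, master_seed,
        )
        rng_split = derive_rng(master_seed, pkey, it, STAGE["split"])
        sel_idx, test_idx = stratified_split(y, split_fraction, rng_split)
        rng_sub = derive_rng(master_seed, pkey, it, STAGE["subsample"])
        if X_pool.shape[1] == 0:
            consensus: list[int] = []
        else:
            consensus, _ = consensus_select(X_pool[sel_idx], y[sel_idx], mrmr, rng_sub)
        snp_ids = tuple(pool.snp_ids[j] for j in consensus)
        iters_sel.append(snp_ids)
        if len(consensus) < 2:
            excluded = True
            n_failed += 1
            continue
        if excluded:
            continue  # trace still accumulates; modeling is moot

        cols = np.asarray(consensus)
        rng_under = derive_rng(master_seed, pkey, it, STAGE["undersample"])
        train_idx = sel_idx[undersample_majority(y[sel_idx], rng_under)]
        fcfg = ForestConfig(
            n_trees=forest.n_trees,
            features_per_split=forest.features_per_split,
            seed=derive_int_seed(master_seed, pkey, it, STAGE["forest"]),
        )
        try:
            model = train_forest(X_pool[np.ix_(train_idx, cols)], y[train_idx], fcfg)
        except TooFewFeaturesError:
            excluded = True
            n_failed += 1
            continue

        scores_test = model.predict_proba(X_pool[np.ix_(test_idx, cols)])
        m_test = metrics_from_scores(scores_test, y[test_idx])
        log_metrics(it, "test20", m_test)
        if validation is not None:
            scores_eval = model.predict_proba(X_val_pool[:, cols])
            y_eval = y_val
            perm_stage = STAGE["permute_validation"]
            m_eval = metrics_from_scores(scores_eval, y_eval)
            log_metrics(it, "validation", m_eval)
        else:
            scores_eval = scores_test
            y_eval = y[test_idx]
            perm_stage = STAGE["permute_test"]
            m_eval = m_test
        y_perm = permute_labels(y_eval, derive_rng(master_seed, pkey, it, perm_stage))
        m_perm = metrics_from_scores(scores_eval, y_perm)
        log_metrics(it, "permuted", m_perm)

        for name in METRIC_NAMES:
            per_metric[name].append(getattr(m_eval, name))
        or_perm.append(m_perm.odds_ratio)
        r2 = nagelkerke_r2(y_eval, scores_eval)
        r2_vals.append(r2.r2)
        r2_sep = r2_sep or r2.separation

    trace = SelectionTrace(pool.pathway_id, iters_sel)
    log_frame = pd.DataFrame(
        log_rows,
        columns=["pathway_id", "iteration", "dataset", "tp", "fn", "fp", "tn",
                 "sens", "spec", "acc", "auc", "or"],
    )
    if excluded or not per_metric["odds_ratio"]:
        result = PathwayResult(
            pathway_id=pool.pathway_id,
            metrics={m: (float("nan"),) * 3 for m in METRIC_NAMES},
            p_raw=float("nan"),
            nagelkerke_r2=float("nan"),
            n_iterations=n_iterations,
            excluded=True,
            n_failed_iterations=n_failed,
            iteration_metrics=log_frame,
        )
        return result, trace

    metrics = {m: metric_ci(per_metric[m]) for m in METRIC_NAMES}
    result = PathwayResult(
        pathway_id=pool.pathway_id,
        metrics=metrics,
        p_raw=pathway_pvalue(per_metric["odds_ratio"], or_perm),
        nagelkerke_r2=float(np.mean(r2_vals)),
        n_iterations=n_iterations,
        excluded=False,
        p_bh=float("nan"),
        r2_separation_flagged=r2_sep,
        or_real=np.asarray(per_metric["odds_ratio"]),
        or_perm=np.asarray(or_perm),
        iteration_metrics=log_frame,
    )
    return result, trace


def run_pwas(
    pools: Sequence[PathwaySnpPool],
    discovery: GenotypeDataset,
    validation: GenotypeDataset | None = None,
    *,
    mrmr: MrmrConfig | None = None,
    forest: ForestConfig | None = None,
    n_iterations: int = 100,
    split_fraction: float = 0.8,
    master_seed: int = 0,
    n_jobs: int = 1,
) -> tuple[list[PathwayResult], dict[str, SelectionTrace]]:
    """Run every pathway and BH-adjust p-values over the non-excluded family.

    Pathways are independent given the per-pathway seed streams, so
    ``n_jobs > 1`` parallelizes over pathways without changing any result.
    """
    kwargs = dict(
        mrmr=mrmr,
        forest=forest,
        n_iterations=n_iterations,
        split_fraction=split_fraction,
        master_seed=master_seed,
    )
    if n_jobs != 1 and len(pools) > 1:
        from joblib import Parallel, delayed

        pairs = Parallel(n_jobs=n_jobs)(
            delayed(run_pathway)(pool, discovery, validation, **kwargs) for pool in pools
        )
    else:
        pairs = [run_pathway(pool, discovery, validation, **kwargs) for pool in pools]
    results = [res for res, _ in pairs]
    traces = {pool.pathway_id: trace for pool, (_, trace) in zip(pools, pairs)}
    tested = [r for r in results if not r.excluded]
    if tested:
        adjusted = bh_adjust([r.p_raw for r in tested])
        for r, p in zip(tested, adjusted):
            r.p_bh = float(p)
    return results, traces


def results_frame(results: Sequence[PathwayResult]) -> pd.DataFrame:
    """Flatten pathway results into a summary table (one row per pathway)."""
    rows = []
    for r in results:
        row: dict[str, object] = {"pathway_id": r.pathway_id}
        for name in METRIC_NAMES:
            mean, lo, hi = r.metrics[name]
            key = "or" if name == "odds_ratio" else name
            row[key] = mean
            row[f"{key}_lo"] = lo
            row[f"{key}_hi"] = hi
        row.update(
            p_raw=r.p_raw,
            p_bh=r.p_bh,
            nagelkerke_r2=r.nagelkerke_r2,
            n_iterations=r.n_iterations,
            excluded=r.excluded,
        )
        rows.append(row)
    return pd.DataFrame(rows)
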