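"""Evaluation statistics: LOOCV, ROC/AUC with permutation p-values, group
tests, correlation tests, and the cut-point accuracy sweep.

Orientation conventions are explicit everywhere: predictions from the linear
model live on the (transformed) log IC50 scale where LOWER means MORE
sensitive, so a sensitivity score for ROC analysis is the negated
prediction; the logistic model's probability of sensitivity is used as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix, PhenotypePanel, align_samples
from .power import PhenotypePowerTransform
from .ridge import LinearRidge

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "StatTestResult",
    "CVResult",
    "CutpointSweep",
    "loocv_linear",
    "roc_auc",
    "permutation_pvalue_auc",
    "two_group_ttest",
    "correlation_test",
    "rank_sum_test",
    "cutpoint_accuracy_sweep",
    "group_medians_ordered",
]


@dataclass
class StatTestResult:
    statistic: float
    p_value: float
    estimate: float
    method: str
    n: int
    details: dict = field(default_factory=dict)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    positive_orientation: str


@dataclass
class CVResult:
    sample_ids: list[str]
    predicted: np.ndarray
    observed: np.ndarray
    pearson: StatTestResult


@dataclass
class CutpointSweep:
    cutpoints: np.ndarray
    accuracy: np.ndarray
    optimal_cutpoint: float
    optimal_accuracy: float
    reference_accuracy: float | None
    above_reference_interval: tuple[float, float] | None


def _orient(scores: np.ndarray, positive_orientation: str) -> np.ndarray:
    if positive_orientation not in ("higher", "lower"):
        raise ValueError("positive_orientation must be 'higher' or 'lower'")
    return -scores if positive_orientation == "lower" else scores


def _auc_from_ranks(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counting one half."""
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    r = stats.rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_auc(
    scores: np.ndarray, labels: np.ndarray, positive_orientation: str = "higher"
) -> ROCResult:
    """ROC curve and AUC by the Mann-Whitney construction.

    ``positive_orientation="lower"`` declares that lower scores indicate the
    positive (sensitive) class, as for predicted IC50.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    s = _orient(scores, positive_orientation)
    auc = _auc_from_ranks(s, labels)

    # curve: sweep thresholds over distinct scores, descending
    order = np.argsort(-s, kind="stable")
    y = labels[order]
    ss = s[order]
    distinct = np.flatnonzero(np.r_[True, np.diff(ss) != 0])
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # index of the last element in each tie group
    last = np.r_[distinct[1:] - 1, len(y) - 1]
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    tpr = np.r_[0.0, tp[last] / n1]
    fpr = np.r_[0.0, fp[last] / n0]
    thresholds = np.r_[np.inf, ss[distinct]]
    return ROCResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
        positive_orientation=positive_orientation,
    )


def permutation_pvalue_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    B: int = 100_000,
    seed: int | np.random.Generator = 0,
    positive_orientation: str = "higher",
) -> StatTestResult:
    """Empirical AUC p-value from random label permutations.

    p is the proportion of permutations whose AUC is at least the observed
    AUC (one-sided toward sensitivity discrimination); the add-one smoothed
    estimate (#+1)/(B+1) is co-reported in ``details``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    s = _orient(scores, positive_orientation)
    n = len(s)
    n1 = int(labels.sum())
    n0 = n - n1
    r = stats.rankdata(s)
    auc_obs = float((r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))

    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    count = 0
    chunk = max(1, min(B, 50_000))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        perm = np.tile(r, (b, 1))
        perm = rng.permuted(perm, axis=1)
        rank_sums = perm[:, :n1].sum(axis=1)
        auc_perm = (rank_sums - n1 * (n1 + 1) / 2.0) / (n1 * n0)
        count += int(np.sum(auc_perm >= auc_obs - 1e-12))
        done += b
    p_raw = count / B
    p_add_one = (count + 1) / (B + 1)
    return StatTestResult(
        statistic=auc_obs,
        p_value=p_raw,
        estimate=auc_obs,
        method="permutation_auc",
        n=n,
        details={"B": B, "p_add_one": p_add_one, "n_positive": n1},
    )


def two_group_ttest(
    values: np.ndarray, groups: np.ndarray, variant: str = "welch"
) -> StatTestResult:
    """Two-sample t-test (Welch by default; pooled available)."""
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {len(uniq)}")
    a = values[groups == uniq[0]]
    b = values[groups == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return StatTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        estimate=float(a.mean() - b.mean()),
        method=f"ttest_{variant}",
        n=len(values),
        details={"group_order": [str(u) for u in uniq]},
    )


def correlation_test(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> StatTestResult:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return StatTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        estimate=float(res.statistic),
        method=method,
        n=len(x),
    )


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> StatTestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test, two-sided.

    Exact enumeration when n1*n0 <= 10,000 and there are no ties; otherwise
    the normal approximation with continuity and tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) * len(b) <= 10_000 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return StatTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        estimate=float(np.median(a) - np.median(b)),
        method=f"ranksum_{method}",
        n=len(a) + len(b),
        details={"U_a": float(res.statistic)},
    )


def cutpoint_accuracy_sweep(
    scores: np.ndarray,
    labels: np.ndarray,
    reference_accuracy: float | None = None,
) -> CutpointSweep:
    """Classification accuracy as the sensitive/resistant cut-point varies.

    Scores BELOW the cut-point are called sensitive (IC50 orientation).
    Candidate cut-points are the midpoints between consecutive distinct
    sorted scores plus +/- infinity. When a reference accuracy is supplied,
    the contiguous cut-point interval beating it is reported.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if len(distinct) > 1 else np.array([])
    cuts = np.r_[-np.inf, mids, np.inf]
    n = len(scores)
    accuracy = np.array(
        [
            float(np.mean((scores < c).astype(int) == labels))
            for c in cuts
        ]
    )
    k = int(np.argmax(accuracy))
    interval = None
    if reference_accuracy is not None:
        above = accuracy > reference_accuracy
        if above.any():
            idx = np.flatnonzero(above)
            interval = (float(cuts[idx[0]]), float(cuts[idx[-1]]))
            if not np.all(np.diff(idx) == 1):
                logger.warning(
                    "cut-points above reference accuracy are not contiguous; "
                    "reporting their envelope"
                )
    return CutpointSweep(
        cutpoints=cuts,
        accuracy=accuracy,
        optimal_cutpoint=float(cuts[k]),
        optimal_accuracy=float(accuracy[k]),
        reference_accuracy=reference_accuracy,
        above_reference_interval=interval,
    )


def group_medians_ordered(
    predictions: np.ndarray,
    categories: np.ndarray,
    category_order: list[str],
) -> tuple[bool, dict[str, float]]:
    """Check that per-category median predictions follow the given order.

    With predictions on the IC50 scale and categories ordered best response
    first, a correct model yields strictly increasing medians.
    """
    predictions = np.asarray(predictions, dtype=float)
    categories = np.asarray([str(c) for c in categories])
    medians: dict[str, float] = {}
    for cat in category_order:
        vals = predictions[categories == cat]
        if len(vals) == 0:
            raise ValueError(f"empty category {cat!r}")
        medians[cat] = float(np.median(vals))
    ordered_vals = [medians[c] for c in category_order]
    is_ordered = bool(np.all(np.diff(ordered_vals) > 0))
    return is_ordered, medians


def loocv_linear(
    train_expr: ExpressionMatrix,
    pheno: PhenotypePanel,
    transform_family: str = "yeo_johnson",
    lambda_method: str = "loo_gcv",
    lambda_grid=None,
    refit_transform: bool = True,
) -> CVResult:
    """Leave-one-out cross-validation of the linear ridge pathway.

    The panel is assumed already homogenized once as a whole; within each
    fold the phenotype transform and the penalty are re-estimated on the
    n-1 training lines (set ``refit_transform=False`` to freeze the
    transform fit on the full panel), the held-out line is predicted, and
    the back-transformed predictions are compared to the measured log IC50s
    with a Pearson correlation test.
    """
    expr, pheno = align_samples(train_expr, pheno)
    n = pheno.n_samples
    if n < 10:
        raise ValueError("LOOCV needs at least 10 samples")
    X = expr.values.T
    y = pheno.ic50
    alpha = {"loo_gcv": "gcv", "cule_deiorio": "cule_deiorio"}[lambda_method]
    frozen = (
        None if refit_transform
        else PhenotypePowerTransform(family=transform_family).fit(y)
    )
    predicted = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pt = (
            frozen if frozen is not None
            else PhenotypePowerTransform(family=transform_family).fit(y[mask])
        )
        z = pt.transform(y[mask])
        model = LinearRidge(alpha=alpha, alpha_grid=lambda_grid).fit(X[mask], z)
        predicted[i] = pt.inverse_transform(model.predict(X[i : i + 1]))[0]
    pearson = correlation_test(predicted, y, method="pearson")
    return CVResult(
        sample_ids=list(pheno.sample_ids),
        predicted=predicted,
        observed=y.copy(),
        pearson=pearson,
    )
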