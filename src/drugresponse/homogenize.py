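"""Merging cell-line and clinical cohorts onto a common, batch-free gene space.

The homogenization pipeline mirrors the transfer-learning setting: the two
cohorts come from different array platforms, so they are (1) restricted to
the shared gene universe, (2) concatenated and adjusted for cohort batch
effects by parametric empirical Bayes, and (3) stripped of the least variable
genes, whose technical noise exceeds any biological signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .combat import BatchRecord, eb_batch_adjust
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "intersect_genes",
    "variance_filter",
    "VarianceFilter",
    "homogenize_pair",
    "HomogenizedPair",
    "FilterRecord",
    "pca_projection",
]


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common genes, in lexicographic order."""
    if len(set(a.gene_ids)) != len(a.gene_ids) or len(set(b.gene_ids)) != len(
        b.gene_ids
    ):
        raise ValueError("intersect_genes requires summarized (unique) gene ids")
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise ValueError("gene universes are disjoint")
    logger.info(
        "intersect_genes: %d common of %d / %d", len(common), a.n_genes, b.n_genes
    )
    return a.subset_genes(common), b.subset_genes(common)


@dataclass
class FilterRecord:
    removed_genes: list[str]
    removed_variances: np.ndarray
    variance_threshold: float
    remove_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.removed_genes, "variance": self.removed_variances}
        )


class VarianceFilter(BaseEstimator, TransformerMixin):
    """Drop the ``remove_fraction`` of genes with smallest variance.

    Variance is the unbiased sample variance across all samples of the matrix
    the filter is fit on; exactly ``floor(remove_fraction * G)`` columns are
    removed, with ties at the cutoff broken by feature-name lexicographic
    order so the result is deterministic.
    """

    def __init__(self, remove_fraction: float = 0.20):
        self.remove_fraction = remove_fraction

    def fit(self, X: np.ndarray, y=None, feature_names=None):
        if not (0.0 <= self.remove_fraction < 1.0):
            raise ValueError("remove_fraction must be in [0, 1)")
        X = np.asarray(X, dtype=float)
        G = X.shape[1]
        self.variances_ = X.var(axis=0, ddof=1)
        names = (
            [str(n) for n in feature_names]
            if feature_names is not None
            else [f"f{i}" for i in range(G)]
        )
        n_remove = int(np.floor(self.remove_fraction * G))
        order = sorted(range(G), key=lambda i: (self.variances_[i], names[i]))
        removed = sorted(order[:n_remove])
        kept = sorted(order[n_remove:])
        self.keep_idx_ = np.array(kept, dtype=int)
        self.removed_idx_ = np.array(removed, dtype=int)
        self.threshold_ = (
            float(self.variances_[order[n_remove - 1]]) if n_remove else -np.inf
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.keep_idx_]


def variance_filter(
    expr: ExpressionMatrix, remove_fraction: float = 0.20
) -> tuple[ExpressionMatrix, FilterRecord]:
    """Remove the lowest-variance genes from a genes x samples matrix."""
    vf = VarianceFilter(remove_fraction=remove_fraction)
    vf.fit(expr.values.T, feature_names=expr.gene_ids)
    kept_genes = [expr.gene_ids[i] for i in vf.keep_idx_]
    removed_genes = [expr.gene_ids[i] for i in vf.removed_idx_]
    logger.info(
        "variance_filter: removed %d/%d genes (fraction %.3g)",
        len(removed_genes), expr.n_genes, remove_fraction,
    )
    out = ExpressionMatrix(
        gene_ids=kept_genes,
        sample_ids=list(expr.sample_ids),
        values=expr.values[vf.keep_idx_, :],
        cohort_label=None if expr.cohort_label is None else list(expr.cohort_label),
    )
    record = FilterRecord(
        removed_genes=removed_genes,
        removed_variances=vf.variances_[vf.removed_idx_],
        variance_threshold=vf.threshold_,
        remove_fraction=remove_fraction,
    )
    return out, record


@dataclass
class HomogenizedPair:
    """Train/test matrices on an identical, adjusted, filtered gene space."""

    train: ExpressionMatrix
    test: ExpressionMatrix
    common_genes: list[str]
    batch_record: BatchRecord
    filter_record: FilterRecord


def homogenize_pair(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    remove_fraction: float = 0.20,
    apply_eb: bool = True,
    eb_tol: float = 1e-4,
    eb_max_iter: int = 100,
) -> HomogenizedPair:
    """Intersect genes, adjust cohort batch effects, filter low-variance genes.

    The two cohorts are treated as one batch each. ``apply_eb=False`` skips
    the empirical-Bayes adjustment (for ablation only) but keeps the rest of
    the pipeline identical.
    """
    a, b = intersect_genes(train, test)
    combined = ExpressionMatrix(
        gene_ids=list(a.gene_ids),
        sample_ids=list(a.sample_ids) + list(b.sample_ids),
        values=np.hstack([a.values, b.values]),
        cohort_label=["train"] * a.n_samples + ["test"] * b.n_samples,
    )
    if apply_eb:
        adjusted, batch_record = eb_batch_adjust(
            combined, tol=eb_tol, max_iter=eb_max_iter
        )
    else:
        adjusted = combined
        batch_record = None
    filtered, filter_record = variance_filter(adjusted, remove_fraction)
    n_train = a.n_samples
    out_train = filtered.subset_samples(filtered.sample_ids[:n_train])
    out_test = filtered.subset_samples(filtered.sample_ids[n_train:])
    out_train.cohort_label = None
    out_test.cohort_label = None
    return HomogenizedPair(
        train=out_train,
        test=out_test,
        common_genes=list(filtered.gene_ids),
        batch_record=batch_record,
        filter_record=filter_record,
    )


def pca_projection(expr: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Project samples onto leading principal components (QC view).

    Samples are observations; genes are mean-centered but not variance
    scaled. Scores come from the SVD of the centered matrix; each component's
    sign is fixed by making its largest-magnitude score positive.
    """
    if expr.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    if n_components > min(expr.n_genes, expr.n_samples):
        raise ValueError(
            f"n_components={n_components} exceeds min(G, N)="
            f"{min(expr.n_genes, expr.n_samples)}"
        )
    X = expr.values.T  # samples x genes
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    for j in range(scores.shape[1]):
        k = int(np.argmax(np.abs(scores[:, j])))
        if scores[k, j] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores,
        index=expr.sample_ids,
        columns=[f"PC{j + 1}" for j in range(scores.shape[1])],
    )
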