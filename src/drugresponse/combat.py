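"""Parametric empirical-Bayes location/scale batch adjustment.

Cross-platform expression data (cell-line arrays vs clinical arrays) carry
per-gene additive and multiplicative batch effects. The adjustment model is
the classic parametric one: for gene g, sample i in batch b,

    Y_gi = alpha_g + gamma_gb + delta_gb * eps_gi,   eps ~ N(0, sigma_g^2)

Per-gene batch estimates (gamma_hat, delta_hat^2) are shrunk toward
batch-level priors — Normal for locations, inverse-gamma for scales, with
hyperparameters estimated across genes by method of moments — via iterated
conditional posterior means, and the data are adjusted as

    Y*_gi = sigma_g * (Z_gi - gamma*_gb) / delta*_gb + alpha_g

with Z the standardized data. No covariates are modeled (none are needed for
the two-cohort design this package targets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["EmpiricalBayesBatchCorrector", "eb_batch_adjust", "BatchRecord"]


@dataclass
class BatchRecord:
    """Per-gene estimates from the EB adjustment, for provenance output."""

    gene_ids: list[str]
    batch_names: list[str]
    gamma_hat: np.ndarray      # raw per-gene batch locations (B x G)
    delta_sq_hat: np.ndarray   # raw per-gene batch variances (B x G)
    gamma_star: np.ndarray     # posterior locations (B x G)
    delta_sq_star: np.ndarray  # posterior variances (B x G)
    alpha: np.ndarray          # per-gene grand effect (G,)
    sigma: np.ndarray          # per-gene pooled SD (G,)
    gamma_bar: np.ndarray      # prior location means (B,)
    tau_sq_bar: np.ndarray     # prior location variances (B,)
    a_prior: np.ndarray        # inverse-gamma shape per batch (B,)
    b_prior: np.ndarray        # inverse-gamma rate per batch (B,)
    dropped_genes: list[str]
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        cols = {"gene_id": self.gene_ids}
        for j, b in enumerate(self.batch_names):
            cols[f"gamma_star_{b}"] = self.gamma_star[j]
            cols[f"delta_star_{b}"] = np.sqrt(self.delta_sq_star[j])
        return pd.DataFrame(cols)


def _moments_inverse_gamma(delta_sq: np.ndarray) -> tuple[float, float]:
    """Method-of-moments (a, b) for an inverse-gamma prior on batch variances."""
    m = float(np.mean(delta_sq))
    s2 = float(np.var(delta_sq, ddof=1))
    a = (2.0 * s2 + m * m) / s2
    b = (m * s2 + m**3) / s2
    return a, b


class EmpiricalBayesBatchCorrector(BaseEstimator):
    """Remove per-gene batch location/scale effects by parametric EB shrinkage.

    Parameters
    ----------
    tol : float
        Relative-change tolerance for the posterior iteration.
    max_iter : int
        Iteration cap for the posterior iteration.
    drop_degenerate : bool
        Drop genes that are constant within some batch before adjusting
        (they carry no usable signal and would divide by zero); an error is
        raised instead when False.

    Notes
    -----
    This transformer adjusts the data it is fit on: call
    :meth:`fit_transform` with the combined matrix (samples x genes) and the
    per-sample batch labels. Fitted attributes use the standard trailing
    underscore (``gamma_star_``, ``delta_sq_star_``, ...).
    """

    def __init__(self, tol: float = 1e-4, max_iter: int = 100,
                 drop_degenerate: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.drop_degenerate = drop_degenerate

    def fit_transform(self, X: np.ndarray, batches) -> np.ndarray:
        """Adjust ``X`` (samples x genes) given per-sample batch labels.

        Returns the adjusted matrix with the same shape, minus any dropped
        degenerate gene columns (see ``kept_features_``).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x genes)")
        batches = np.asarray([str(b) for b in batches])
        if len(batches) != X.shape[0]:
            raise ValueError("batch labels must match the number of samples")
        names, inverse = np.unique(batches, return_inverse=True)
        if len(names) < 2:
            raise ValueError("batch adjustment needs at least two batches")
        counts = np.bincount(inverse)
        if np.any(counts < 2):
            small = [str(names[i]) for i in np.flatnonzero(counts < 2)]
            raise ValueError(f"every batch needs >=2 samples; too small: {small}")

        n, G = X.shape
        B = len(names)
        masks = [inverse == j for j in range(B)]

        # degenerate genes: constant within some batch
        within_var = np.stack([X[m].var(axis=0, ddof=1) for m in masks])
        degenerate = np.any(within_var <= 0.0, axis=0)
        self.kept_features_ = np.flatnonzero(~degenerate)
        self.dropped_features_ = np.flatnonzero(degenerate)
        if degenerate.any():
            if not self.drop_degenerate:
                raise ValueError(
                    f"{int(degenerate.sum())} genes constant within a batch"
                )
            logger.warning(
                "dropping %d genes constant within a batch before EB adjustment",
                int(degenerate.sum()),
            )
            X = X[:, ~degenerate]
            G = X.shape[1]

        # step 1: grand effect, batch means, pooled variance; standardize
        batch_means = np.stack([X[m].mean(axis=0) for m in masks])   # B x G
        w = counts / n
        alpha = w @ batch_means                                       # G,
        resid = X - batch_means[inverse]
        sigma_sq = (resid**2).sum(axis=0) / n
        if np.any(sigma_sq <= 0.0):
            raise ValueError("gene with zero pooled variance after batch fit")
        sigma = np.sqrt(sigma_sq)
        Z = (X - alpha) / sigma

        # step 2: per-batch raw estimates on Z + method-of-moments hyperpriors
        gamma_hat = np.stack([Z[m].mean(axis=0) for m in masks])      # B x G
        delta_sq_hat = np.stack([Z[m].var(axis=0, ddof=1) for m in masks])
        gamma_bar = gamma_hat.mean(axis=1)
        tau_sq_bar = gamma_hat.var(axis=1, ddof=1)
        ab = [_moments_inverse_gamma(delta_sq_hat[j]) for j in range(B)]
        a_prior = np.array([x[0] for x in ab])
        b_prior = np.array([x[1] for x in ab])

        # step 3: iterate conditional posterior means to convergence
        gamma_star = gamma_hat.copy()
        delta_sq_star = delta_sq_hat.copy()
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            change = 0.0
            for j in range(B):
                nb = counts[j]
                g_new = (
                    nb * tau_sq_bar[j] * gamma_hat[j]
                    + delta_sq_star[j] * gamma_bar[j]
                ) / (nb * tau_sq_bar[j] + delta_sq_star[j])
                ssq = ((Z[masks[j]] - g_new) ** 2).sum(axis=0)
                d_new = (b_prior[j] + 0.5 * ssq) / (nb / 2.0 + a_prior[j] - 1.0)
                change = max(
                    change,
                    float(np.max(np.abs(g_new - gamma_star[j])
                                 / np.maximum(np.abs(gamma_star[j]), 1e-12))),
                    float(np.max(np.abs(d_new - delta_sq_star[j])
                                 / np.maximum(np.abs(delta_sq_star[j]), 1e-12))),
                )
                gamma_star[j] = g_new
                delta_sq_star[j] = d_new
            if change < self.tol:
                break

        # step 4: adjust
        adjusted = np.empty_like(Z)
        for j in range(B):
            adjusted[masks[j]] = (Z[masks[j]] - gamma_star[j]) / np.sqrt(
                delta_sq_star[j]
            )
        adjusted = adjusted * sigma + alpha

        self.batch_names_ = [str(b) for b in names]
        self.batch_index_ = inverse
        self.alpha_ = alpha
        self.sigma_ = sigma
        self.gamma_hat_ = gamma_hat
        self.delta_sq_hat_ = delta_sq_hat
        self.gamma_star_ = gamma_star
        self.delta_sq_star_ = delta_sq_star
        self.gamma_bar_ = gamma_bar
        self.tau_sq_bar_ = tau_sq_bar
        self.a_prior_ = a_prior
        self.b_prior_ = b_prior
        self.n_iter_ = n_iter
        return adjusted


def eb_batch_adjust(
    combined: ExpressionMatrix,
    batch: list[str] | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[ExpressionMatrix, BatchRecord]:
    """Adjust a combined genes x samples matrix for batch effects.

    ``batch`` defaults to the matrix's ``cohort_label``. Genes constant within
    a batch are dropped with a warning. Returns the adjusted matrix and the
    full per-gene provenance record.
    """
    if batch is None:
        batch = combined.cohort_label
    if batch is None:
        raise ValueError("need batch labels (or a cohort_label on the matrix)")
    est = EmpiricalBayesBatchCorrector(tol=tol, max_iter=max_iter)
    adjusted = est.fit_transform(combined.values.T, batch)
    kept = [combined.gene_ids[i] for i in est.kept_features_]
    dropped = [combined.gene_ids[i] for i in est.dropped_features_]
    out = ExpressionMatrix(
        gene_ids=kept,
        sample_ids=list(combined.sample_ids),
        values=adjusted.T,
        cohort_label=None
        if combined.cohort_label is None
        else list(combined.cohort_label),
    )
    record = BatchRecord(
        gene_ids=kept,
        batch_names=est.batch_names_,
        gamma_hat=est.gamma_hat_,
        delta_sq_hat=est.delta_sq_hat_,
        gamma_star=est.gamma_star_,
        delta_sq_star=est.delta_sq_star_,
        alpha=est.alpha_,
        sigma=est.sigma_,
        gamma_bar=est.gamma_bar_,
        tau_sq_bar=est.tau_sq_bar_,
        a_prior=est.a_prior_,
        b_prior=est.b_prior_,
        dropped_genes=dropped,
        n_iter=est.n_iter_,
    )
    return out, record
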