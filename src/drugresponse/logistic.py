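"""Logistic ridge regression for targeted agents with unreliable IC50s.

For many targeted drugs most cell lines never respond within the screened
concentration window, so their IC50s are extrapolated and noise-dominated;
fitting a linear model to those values mostly fits noise. The alternative
pathway keeps only the rank information that is trustworthy: the most
sensitive lines (reliably measured) versus the most resistant, a per-gene
t-test feature-selection step, and an L2-penalized logistic fit whose output
is the predicted log-odds of drug sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .matrix import PhenotypePanel
from .ridge import default_lambda_grid, _standardize

logger = logging.getLogger(__name__)

__all__ = [
    "binarize_training",
    "rank_genes_by_ttest",
    "LogisticRidge",
    "fit_logistic_ridge",
    "BinarizationResult",
    "SelectionRecord",
]


@dataclass
class BinarizationResult:
    """Sensitive/resistant split of a phenotype panel by IC50 rank."""

    sample_ids: list[str]     # kept samples, original panel order
    labels: np.ndarray        # 1 = sensitive, 0 = resistant
    dropped_ids: list[str]    # middle-of-the-range lines excluded
    ic50_cut_sensitive: float  # largest IC50 labeled sensitive
    ic50_cut_resistant: float  # smallest IC50 labeled resistant


def binarize_training(
    pheno: PhenotypePanel, n_sensitive: int = 15, n_resistant: int = 55
) -> BinarizationResult:
    """Label the ``n_sensitive`` lowest-IC50 lines sensitive and the
    ``n_resistant`` highest resistant; drop the middle.

    Ties at either boundary are broken by sample-id lexicographic order
    (deterministic, logged). Missing IC50s must be filtered beforehand.
    """
    if n_sensitive < 1 or n_resistant < 1:
        raise ValueError("n_sensitive and n_resistant must be >= 1")
    n = pheno.n_samples
    if n_sensitive + n_resistant > n:
        raise ValueError(
            f"n_sensitive + n_resistant = {n_sensitive + n_resistant} exceeds "
            f"panel size {n}"
        )
    if not np.all(np.isfinite(pheno.ic50)):
        raise ValueError("panel contains missing IC50s; align/filter first")
    order = sorted(range(n), key=lambda i: (pheno.ic50[i], pheno.sample_ids[i]))
    sens = set(order[:n_sensitive])
    resist = set(order[n - n_resistant:])
    if len(np.unique(pheno.ic50)) < n:
        logger.info("binarize_training: IC50 ties broken by sample id")
    kept = [i for i in range(n) if i in sens or i in resist]
    labels = np.array([1 if i in sens else 0 for i in kept], dtype=int)
    dropped = [pheno.sample_ids[i] for i in range(n) if i not in sens and i not in resist]
    return BinarizationResult(
        sample_ids=[pheno.sample_ids[i] for i in kept],
        labels=labels,
        dropped_ids=dropped,
        ic50_cut_sensitive=float(pheno.ic50[order[n_sensitive - 1]]),
        ic50_cut_resistant=float(pheno.ic50[order[n - n_resistant]]),
    )


@dataclass
class SelectionRecord:
    """Per-gene differential-expression ranking used for feature selection."""

    table: pd.DataFrame  # gene_id, t, p, rank (full universe)
    selected: list[str]  # top-k gene ids, best first
    selected_idx: np.ndarray
    k: int
    variant: str


def rank_genes_by_ttest(
    X: np.ndarray,
    labels: np.ndarray,
    gene_ids=None,
    k: int = 1000,
    variant: str = "pooled",
) -> SelectionRecord:
    """Rank genes by two-sample t between classes; return the top ``k``.

    ``X`` is samples x genes. The default statistic is the pooled-variance
    (equal-variance) t, the convention of row-wise array statistics; Welch is
    available via ``variant="welch"``. Ties in p are broken by gene-id
    lexicographic order.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int)
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("both classes need >= 2 samples for t-tests")
    G = X.shape[1]
    ids = (
        [str(g) for g in gene_ids] if gene_ids is not None
        else [f"g{i}" for i in range(G)]
    )
    A = X[labels == 1]
    B = X[labels == 0]
    m1, m0 = A.mean(axis=0), B.mean(axis=0)
    v1 = A.var(axis=0, ddof=1)
    v0 = B.var(axis=0, ddof=1)
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        df = np.full(G, n1 + n0 - 2, dtype=float)
    else:
        se = np.sqrt(v1 / n1 + v0 / n0)
        with np.errstate(invalid="ignore", divide="ignore"):
            df = (v1 / n1 + v0 / n0) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
            )
        df = np.where(np.isfinite(df), df, n1 + n0 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, (m1 - m0) / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    order = sorted(range(G), key=lambda i: (p[i], -abs(t[i]), ids[i]))
    rank = np.empty(G, dtype=int)
    for r, i in enumerate(order):
        rank[i] = r + 1
    if k > G:
        logger.warning("rank_genes_by_ttest: k=%d > G=%d; returning all genes", k, G)
    k_eff = min(k, G)
    selected_idx = np.array(order[:k_eff], dtype=int)
    table = pd.DataFrame({"gene_id": ids, "t": t, "p": p, "rank": rank})
    return SelectionRecord(
        table=table,
        selected=[ids[i] for i in selected_idx],
        selected_idx=selected_idx,
        k=k_eff,
        variant=variant,
    )


def _penalized_nll(
    beta0: float, beta: np.ndarray, eta: np.ndarray, y: np.ndarray, lam: float
) -> float:
    # -log L + (lam/2)||beta||^2, intercept unpenalized; logaddexp for stability
    return float(
        np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * lam * beta @ beta
    )


def _newton_primal(
    X: np.ndarray, y: np.ndarray, lam: float, tol: float, max_iter: int
):
    """Damped Newton on (intercept, beta) in the primal parametrization."""
    n, p = X.shape
    A = np.hstack([np.ones((n, 1)), X])
    pen = np.full(p + 1, lam)
    pen[0] = 0.0
    theta = np.zeros(p + 1)
    eta = A @ theta
    obj = _penalized_nll(theta[0], theta[1:], eta, y, lam)
    path = [obj]
    for it in range(1, max_iter + 1):
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(prob * (1.0 - prob), 1e-10)
        grad = A.T @ (y - prob) - pen * theta
        H = (A * w[:, None]).T @ A + np.diag(pen)
        step = np.linalg.solve(H, grad)
        t_step = 1.0
        for _ in range(30):
            cand = theta + t_step * step
            eta_c = A @ cand
            obj_c = _penalized_nll(cand[0], cand[1:], eta_c, y, lam)
            if obj_c <= obj:
                break
            t_step *= 0.5
        theta, eta = cand, eta_c
        path.append(obj_c)
        if abs(obj - obj_c) <= tol * (abs(obj) + 1e-12):
            return theta[0], theta[1:], True, it, np.array(path)
        obj = obj_c
    return theta[0], theta[1:], False, max_iter, np.array(path)


def _newton_dual(
    X: np.ndarray, y: np.ndarray, lam: float, tol: float, max_iter: int
):
    """Kernel (dual) Newton for p >> n: beta = X' alpha, K = X X'."""
    n = X.shape[0]
    K = X @ X.T
    theta = np.zeros(n + 1)  # (beta0, alpha)
    eta = np.zeros(n)

    def pen_term(alpha):
        return 0.5 * lam * float(alpha @ K @ alpha)

    def obj_fn(eta, alpha):
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta)) + pen_term(alpha)

    obj = obj_fn(eta, theta[1:])
    path = [obj]
    jitter = 1e-10 * (np.trace(K) / n + 1.0)
    for it in range(1, max_iter + 1):
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(prob * (1.0 - prob), 1e-10)
        r = y - prob
        grad = np.concatenate([[r.sum()], K @ r - lam * (K @ theta[1:])])
        H = np.empty((n + 1, n + 1))
        H[0, 0] = w.sum()
        H[0, 1:] = w @ K
        H[1:, 0] = H[0, 1:]
        H[1:, 1:] = (K * w[None, :]) @ K + lam * K + jitter * np.eye(n)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t_step = 1.0
        for _ in range(30):
            cand = theta + t_step * step
            eta_c = cand[0] + K @ cand[1:]
            obj_c = obj_fn(eta_c, cand[1:])
            if obj_c <= obj:
                break
            t_step *= 0.5
        theta, eta = cand, eta_c
        path.append(obj_c)
        if abs(obj - obj_c) <= tol * (abs(obj) + 1e-12):
            return theta[0], X.T @ theta[1:], True, it, np.array(path)
        obj = obj_c
    return theta[0], X.T @ theta[1:], False, max_iter, np.array(path)


class LogisticRidge(BaseEstimator, ClassifierMixin):
    """L2-penalized logistic regression via damped Newton / IRLS.

    Maximizes the Bernoulli log-likelihood minus ``(alpha/2)||beta||^2`` with
    an unpenalized intercept. When features outnumber samples the kernel dual
    parametrization is used (identical solution, n x n systems). The penalty
    is selected by 10-fold cross-validated deviance over a log-spaced grid
    when ``alpha="cv"``.

    Fitted attributes: ``coef_``, ``intercept_``, ``alpha_``, ``n_iter_``,
    ``converged_``, ``objective_path_`` (penalized negative log-likelihood per
    Newton iteration, nonincreasing), ``x_mean_``, ``x_scale_``,
    ``cv_deviance_`` (CV only).
    """

    def __init__(
        self,
        alpha: float | str = "cv",
        alpha_grid=None,
        cv: int = 10,
        tol: float = 1e-8,
        max_iter: int = 100,
        standardize: bool = True,
        random_state: int | None = 0,
    ):
        self.alpha = alpha
        self.alpha_grid = alpha_grid
        self.cv = cv
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize
        self.random_state = random_state

    def _solve(self, Xs: np.ndarray, y: np.ndarray, lam: float):
        n, p = Xs.shape
        if p > n:
            return _newton_dual(Xs, y, lam, self.tol, self.max_iter)
        return _newton_primal(Xs, y, lam, self.tol, self.max_iter)

    def _cv_select(self, Xs: np.ndarray, y: np.ndarray, grid: np.ndarray) -> float:
        n = len(y)
        folds = min(self.cv, n)
        rng = np.random.default_rng(self.random_state)
        # stratified-ish deterministic assignment: shuffle within class
        assign = np.empty(n, dtype=int)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            assign[idx] = np.arange(len(idx)) % folds
        dev = np.zeros(len(grid))
        for f in range(folds):
            tr = assign != f
            te = ~tr
            if y[tr].min() == y[tr].max():
                continue  # degenerate fold; skip
            for i, lam in enumerate(grid):
                b0, beta, _, _, _ = self._solve(Xs[tr], y[tr], lam)
                eta = b0 + Xs[te] @ beta
                dev[i] += 2.0 * float(
                    np.sum(np.logaddexp(0.0, eta) - y[te] * eta)
                )
        self.cv_deviance_ = dev
        return float(grid[int(np.argmin(dev))])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticRidge":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(float).ravel()
        if set(np.unique(y)) != {0.0, 1.0}:
            raise ValueError("labels must contain both classes, coded 0/1")
        if self.standardize:
            Xs, self.x_mean_, self.x_scale_ = _standardize(X)
        else:
            Xs = X
            self.x_mean_ = np.zeros(X.shape[1])
            self.x_scale_ = np.ones(X.shape[1])
        if isinstance(self.alpha, str):
            if self.alpha != "cv":
                raise ValueError(f"unknown alpha selector {self.alpha!r}")
            grid = (
                default_lambda_grid()
                if self.alpha_grid is None
                else np.sort(np.asarray(self.alpha_grid, dtype=float))
            )
            self.alpha_ = self._cv_select(Xs, y, grid)
        else:
            if self.alpha <= 0:
                raise ValueError("alpha must be > 0 (finite coefficients)")
            self.alpha_ = float(self.alpha)
        b0, beta, converged, n_iter, path = self._solve(Xs, y, self.alpha_)
        if not converged:
            raise RuntimeError(
                f"logistic ridge did not converge in {self.max_iter} Newton "
                f"iterations (last objective change "
                f"{abs(path[-1] - path[-2]):.3e}; alpha={self.alpha_:g})"
            )
        self.intercept_ = float(b0)
        self.coef_ = beta
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.objective_path_ = path
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return ((X - self.x_mean_) / self.x_scale_) @ self.coef_ + self.intercept_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        # clip keeps probabilities in the open interval under float saturation
        eta = np.clip(self.decision_function(X), -700, 700)
        p1 = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-15, 1.0 - 1e-15)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.0).astype(int)


def fit_logistic_ridge(
    X: np.ndarray,
    labels: np.ndarray,
    ridge_lambda: float | str = "cv",
    **kwargs,
) -> LogisticRidge:
    """Fit a :class:`LogisticRidge` (thin functional wrapper)."""
    return LogisticRidge(alpha=ridge_lambda, **kwargs).fit(X, labels)
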