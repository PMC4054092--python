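"""Seeded generators for cell-line panels and batch-shifted clinical cohorts.

These emulate the statistical structure the pipeline assumes about real
pharmacogenomic data: per-gene log2 baselines with heterogeneous variances, a
sparse linear gene -> log-IC50 signal with additive noise tuned to a target
R^2, a clinical cohort sharing the signal but carrying per-gene
location/scale batch shifts and a partially overlapping gene universe, and a
targeted-agent regime where only an extreme-sensitive tail of the panel has
reliably measured IC50s. Every generator is a pure function of its
parameters and seed, and the returned :class:`SyntheticTruth` suffices to
recompute every latent quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import (
    DEFAULT_ORDINAL_CATEGORIES,
    ClinicalResponseTable,
    ExpressionMatrix,
    PhenotypePanel,
    ResponseKind,
)

__all__ = [
    "SyntheticTruth",
    "generate_cell_line_panel",
    "generate_clinical_cohort",
    "generate_targeted_agent_panel",
]


#: number of shared expression programs (latent factors) and the fraction of
#: each gene's variance they carry; the scale of leading-component variance
#: in real array cohorts, and what makes whole-genome ridge transfer work
N_FACTORS = 15
FACTOR_VARIANCE_FRACTION = 0.65


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated panel (and, once drawn, its cohort)."""

    gene_ids: list[str]
    gene_mean: np.ndarray          # per-gene baseline (log2 scale)
    gene_sd: np.ndarray            # per-gene total expression SD
    loadings: np.ndarray           # genes x factors co-expression loadings
    unique_sd: np.ndarray          # per-gene SD of the non-shared component
    beta_true: np.ndarray          # per-gene coefficient (0 off the causal set)
    causal_gene_ids: list[str]
    noise_sd: float                # SD of the additive IC50 noise
    latent_sensitivity: np.ndarray  # per-sample X beta (training panel)
    seed: int
    target_r2: float
    batch_location: np.ndarray | None = None   # per-gene shift (clinical cohort)
    batch_scale: np.ndarray | None = None      # per-gene positive scale
    latent_clinical: np.ndarray | None = None  # per-patient X beta
    reliable_ids: list[str] | None = field(default=None)  # targeted-agent panel


def _factor_loadings(
    rng: np.random.Generator, sd: np.ndarray, n_factors: int, shared_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Random-direction loadings giving each gene ``shared_frac`` of its
    variance from the common factors."""
    G = len(sd)
    raw = rng.standard_normal((G, n_factors))
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    loadings = raw * (sd * np.sqrt(shared_frac))[:, None]
    unique_sd = sd * np.sqrt(1.0 - shared_frac)
    return loadings, unique_sd


def _draw_expression(
    rng: np.random.Generator,
    mu: np.ndarray,
    loadings: np.ndarray,
    unique_sd: np.ndarray,
    n: int,
) -> np.ndarray:
    """Genes x samples draw from the factor model
    x = mu + L f + unique noise."""
    G, k = loadings.shape
    factors = rng.standard_normal((k, n))
    return (
        mu[:, None]
        + loadings @ factors
        + unique_sd[:, None] * rng.standard_normal((G, n))
    )


def generate_cell_line_panel(
    n_genes: int = 1000,
    n_lines: int = 200,
    n_causal: int = 30,
    target_r2: float = 0.7,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PhenotypePanel, SyntheticTruth]:
    """Simulate a cell-line training panel with a known sparse signal.

    Per-gene baselines are N(7, 1.5^2) on the log2 scale with per-gene total
    SDs U(0.2, 1.5), of which 65% of the variance is shared across genes
    through 15 latent co-expression factors; ``n_causal`` genes get
    coefficients of random sign and magnitude U(0.5, 1); log IC50 = X beta +
    noise with the noise variance set so that var(X beta)/var(y) hits
    ``target_r2`` (beta = 0 when the target is 0).
    """
    if not (0 < n_causal <= n_genes) and target_r2 > 0:
        raise ValueError("need 0 < n_causal <= n_genes")
    if not (0.0 <= target_r2 < 1.0):
        raise ValueError("target_r2 must be in [0, 1)")
    if n_lines < 2 or n_genes < 1:
        raise ValueError("need n_lines >= 2 and n_genes >= 1")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"CL{i:04d}" for i in range(n_lines)]
    mu = rng.normal(7.0, 1.5, size=n_genes)
    sd = rng.uniform(0.2, 1.5, size=n_genes)
    loadings, unique_sd = _factor_loadings(
        rng, sd, N_FACTORS, FACTOR_VARIANCE_FRACTION
    )
    values = _draw_expression(rng, mu, loadings, unique_sd, n_lines)

    beta = np.zeros(n_genes)
    if target_r2 > 0.0:
        causal = rng.choice(n_genes, size=n_causal, replace=False)
        beta[causal] = rng.uniform(0.5, 1.0, size=n_causal) * rng.choice(
            [-1.0, 1.0], size=n_causal
        )
    latent = values.T @ beta
    signal_var = float(np.var(latent, ddof=1)) if target_r2 > 0 else 0.0
    if target_r2 > 0.0:
        noise_sd = float(np.sqrt(signal_var * (1.0 - target_r2) / target_r2))
    else:
        noise_sd = 1.0
    ic50 = latent + noise_sd * rng.standard_normal(n_lines)

    truth = SyntheticTruth(
        gene_ids=gene_ids,
        gene_mean=mu,
        gene_sd=sd,
        loadings=loadings,
        unique_sd=unique_sd,
        beta_true=beta,
        causal_gene_ids=[gene_ids[i] for i in np.flatnonzero(beta)],
        noise_sd=noise_sd,
        latent_sensitivity=latent,
        seed=seed,
        target_r2=target_r2,
    )
    expr = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)
    pheno = PhenotypePanel(drug_name="simdrug", sample_ids=sample_ids, ic50=ic50)
    return expr, pheno, truth


def generate_clinical_cohort(
    truth: SyntheticTruth,
    n_patients: int = 40,
    gene_overlap: float = 0.9,
    response: str = "binary",
    seed: int = 0,
    batch_location: np.ndarray | None = None,
    batch_scale: np.ndarray | None = None,
    flip_noise: float = 0.1,
) -> tuple[ExpressionMatrix, ClinicalResponseTable, SyntheticTruth]:
    """Draw a clinical cohort sharing the panel's signal but batch-shifted.

    Patients follow the panel's expression model; each gene is then distorted
    by a per-gene location shift (default N(0,1)) and scale factor (default
    U(0.7, 1.4)) about the gene's baseline mean, and a random
    ``1 - gene_overlap`` fraction of genes is dropped to emulate platform
    mismatch. The clinical response derives from the latent X beta: binary by
    median split (responder = more sensitive) with label-flip noise, ordinal
    by latent quintiles (CR best), continuous as a log-normal
    months-to-progression analogue decreasing in X beta.

    Returns the observed expression, the response table, and a copy of the
    truth updated with the batch vectors and the patients' latent signal.
    """
    if not (0.0 < gene_overlap <= 1.0):
        raise ValueError("gene_overlap must be in (0, 1]")
    kind = ResponseKind(response)
    rng = np.random.default_rng(seed)
    G = len(truth.gene_ids)
    sample_ids = [f"PT{i:04d}" for i in range(n_patients)]
    clean = _draw_expression(
        rng, truth.gene_mean, truth.loadings, truth.unique_sd, n_patients
    )
    latent = clean.T @ truth.beta_true

    loc = (
        rng.standard_normal(G) if batch_location is None
        else np.asarray(batch_location, dtype=float)
    )
    scale = (
        rng.uniform(0.7, 1.4, size=G) if batch_scale is None
        else np.asarray(batch_scale, dtype=float)
    )
    if np.any(scale <= 0):
        raise ValueError("batch_scale must be positive")
    shifted = (
        truth.gene_mean[:, None]
        + scale[:, None] * (clean - truth.gene_mean[:, None])
        + loc[:, None]
    )

    n_keep = max(1, int(round(gene_overlap * G)))
    keep = np.sort(rng.choice(G, size=n_keep, replace=False))
    expr = ExpressionMatrix(
        gene_ids=[truth.gene_ids[i] for i in keep],
        sample_ids=sample_ids,
        values=shifted[keep, :],
    )

    if kind is ResponseKind.BINARY:
        responder = (latent < np.median(latent)).astype(int)
        if flip_noise > 0:
            flip = rng.random(n_patients) < flip_noise
            responder = np.where(flip, 1 - responder, responder)
        table = ClinicalResponseTable(
            sample_ids=sample_ids, response=responder, response_kind=kind
        )
    elif kind is ResponseKind.ORDINAL:
        qs = np.quantile(latent, [0.2, 0.4, 0.6, 0.8])
        cat = np.array(DEFAULT_ORDINAL_CATEGORIES, dtype=object)[
            np.searchsorted(qs, latent)
        ]
        table = ClinicalResponseTable(
            sample_ids=sample_ids,
            response=cat,
            response_kind=kind,
            categories=list(DEFAULT_ORDINAL_CATEGORIES),
        )
    else:
        z = (latent - latent.mean()) / max(latent.std(ddof=1), 1e-12)
        months = 6.0 * np.exp(0.5 * (-z + 0.5 * rng.standard_normal(n_patients)))
        table = ClinicalResponseTable(
            sample_ids=sample_ids, response=months, response_kind=kind
        )

    cohort_truth = replace(
        truth, batch_location=loc, batch_scale=scale, latent_clinical=latent
    )
    return expr, table, cohort_truth


def generate_targeted_agent_panel(
    n_genes: int = 1000,
    n_lines: int = 70,
    n_reliable: int = 15,
    seed: int = 0,
    n_causal: int = 30,
) -> tuple[ExpressionMatrix, PhenotypePanel, SyntheticTruth]:
    """Simulate a targeted-agent screen: only an extreme-sensitive tail of
    the panel responds within the screening window.

    The ``n_reliable`` lines with lowest latent X beta get accurately
    measured IC50s (noise SD 10% of the signal SD); the remainder get
    extrapolated values — offset above the screening window by two noise SDs
    and noise-dominated (noise SD 10x the signal SD), so their rank carries
    almost no information about the latent signal.
    """
    if not (1 <= n_reliable < n_lines):
        raise ValueError("need 1 <= n_reliable < n_lines")
    expr, _, truth = generate_cell_line_panel(
        n_genes=n_genes, n_lines=n_lines, n_causal=n_causal,
        target_r2=0.7, seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    latent = truth.latent_sensitivity
    signal_sd = float(np.std(latent, ddof=1))
    order = np.argsort(latent, kind="stable")
    reliable = np.zeros(n_lines, dtype=bool)
    reliable[order[:n_reliable]] = True

    ic50 = np.empty(n_lines)
    ic50[reliable] = latent[reliable] + 0.1 * signal_sd * rng.standard_normal(
        n_reliable
    )
    noise_sd = 10.0 * signal_sd
    n_unrel = n_lines - n_reliable
    ic50[~reliable] = (
        latent[~reliable]
        + 2.0 * noise_sd
        + noise_sd * rng.standard_normal(n_unrel)
    )
    pheno = PhenotypePanel(
        drug_name="simtargeted", sample_ids=list(expr.sample_ids), ic50=ic50
    )
    truth = replace(
        truth,
        noise_sd=noise_sd,
        reliable_ids=[expr.sample_ids[i] for i in np.flatnonzero(reliable)],
    )
    return expr, pheno, truth
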