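"""End-to-end composition: homogenize, fit, predict.

The full method is: intersect gene universes, adjust the cohort batch effect
by parametric empirical Bayes, drop the least-variable genes, fit the
penalized model on the cell lines (linear ridge on the power-transformed log
IC50, or logistic ridge on a sensitive/resistant split with t-test feature
selection for targeted agents), and apply it to the clinical cohort.
Everything is deterministic given the inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np

from .homogenize import HomogenizedPair, homogenize_pair
from .logistic import (
    BinarizationResult,
    LogisticRidge,
    SelectionRecord,
    binarize_training,
    fit_logistic_ridge,
    rank_genes_by_ttest,
)
from .matrix import ExpressionMatrix, PhenotypePanel, align_samples
from .power import PhenotypePowerTransform
from .ridge import LinearRidge, fit_linear_ridge

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionTable",
    "LinearModelBundle",
    "LogisticModelBundle",
    "predict_linear",
    "predict_logistic",
    "train_and_predict",
    "PipelineResult",
]


@dataclass
class PredictionTable:
    """Per-patient predicted sensitivity.

    For the linear pathway ``predicted`` is on the transformed log IC50
    scale (lower = more sensitive) and ``probability`` is None; for the
    logistic pathway ``predicted`` is the log-odds of sensitivity and
    ``probability`` its logistic map (higher = more sensitive).
    """

    sample_ids: list[str]
    predicted: np.ndarray
    probability: np.ndarray | None = None
    model_provenance: dict | None = None


@dataclass
class LinearModelBundle:
    """A fitted linear ridge model plus everything needed to apply it."""

    gene_ids: list[str]
    model: LinearRidge
    transform: PhenotypePowerTransform

    @property
    def coefficients(self) -> np.ndarray:
        return self.model.coef_

    @property
    def intercept(self) -> float:
        return self.model.intercept_

    @property
    def ridge_lambda(self) -> float:
        return self.model.alpha_


@dataclass
class LogisticModelBundle:
    """A fitted logistic ridge model on its selected feature set."""

    gene_ids: list[str]
    model: LogisticRidge
    selection_record: SelectionRecord
    class_definition: BinarizationResult


def _check_genes(model_genes: list[str], expr: ExpressionMatrix) -> ExpressionMatrix:
    missing = sorted(set(model_genes) - set(expr.gene_ids))
    if missing:
        raise ValueError(
            f"test matrix is missing {len(missing)} model genes "
            f"(first: {missing[:10]})"
        )
    return expr.subset_genes(model_genes)


def predict_linear(
    bundle: LinearModelBundle,
    expr_test: ExpressionMatrix,
    back_transform: bool = False,
) -> PredictionTable:
    """Apply a linear ridge bundle to a test expression matrix.

    Predictions are on the transformed log IC50 scale (lower = more
    sensitive); ``back_transform=True`` maps them back to the log IC50
    scale through the stored power transform.
    """
    expr = _check_genes(bundle.gene_ids, expr_test)
    pred = bundle.model.predict(expr.values.T)
    if back_transform:
        pred = bundle.transform.inverse_transform(pred)
    return PredictionTable(
        sample_ids=list(expr.sample_ids),
        predicted=pred,
        model_provenance={
            "mode": "linear",
            "ridge_lambda": bundle.ridge_lambda,
            "transform_family": bundle.transform.family,
            "transform_lambda": bundle.transform.lambda_,
            "n_genes": len(bundle.gene_ids),
            "back_transformed": back_transform,
        },
    )


def predict_logistic(
    bundle: LogisticModelBundle, expr_test: ExpressionMatrix
) -> PredictionTable:
    """Apply a logistic ridge bundle; returns log-odds and probabilities."""
    expr = _check_genes(bundle.gene_ids, expr_test)
    log_odds = bundle.model.decision_function(expr.values.T)
    prob = bundle.model.predict_proba(expr.values.T)[:, 1]
    return PredictionTable(
        sample_ids=list(expr.sample_ids),
        predicted=log_odds,
        probability=prob,
        model_provenance={
            "mode": "logistic",
            "ridge_lambda": bundle.model.alpha_,
            "n_genes": len(bundle.gene_ids),
            "n_sensitive": int(bundle.class_definition.labels.sum()),
            "n_resistant": int(
                (1 - bundle.class_definition.labels).sum()
            ),
        },
    )


@dataclass
class PipelineResult:
    predictions: PredictionTable
    model: LinearModelBundle | LogisticModelBundle
    homogenized: HomogenizedPair
    config: dict


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def train_and_predict(
    train_expr: ExpressionMatrix,
    pheno: PhenotypePanel,
    test_expr: ExpressionMatrix,
    mode: str = "linear",
    remove_fraction: float = 0.20,
    apply_eb: bool = True,
    transform_family: str = "yeo_johnson",
    lambda_method: str = "loo_gcv",
    lambda_grid=None,
    n_sensitive: int = 15,
    n_resistant: int = 55,
    k_features: int = 1000,
    ttest_variant: str = "pooled",
    seed: int = 0,
) -> PipelineResult:
    """Run the full train-on-cell-lines, predict-on-patients pipeline.

    ``mode="linear"`` fits the power-transform + linear ridge pathway;
    ``mode="logistic"`` the binarize + t-test-select + logistic ridge
    pathway for targeted agents.
    """
    if mode not in ("linear", "logistic"):
        raise ValueError("mode must be 'linear' or 'logistic'")
    config = {
        "mode": mode,
        "remove_fraction": remove_fraction,
        "apply_eb": apply_eb,
        "transform_family": transform_family,
        "lambda_method": lambda_method,
        "lambda_grid": None if lambda_grid is None else list(map(float, lambda_grid)),
        "n_sensitive": n_sensitive,
        "n_resistant": n_resistant,
        "k_features": k_features,
        "ttest_variant": ttest_variant,
        "seed": seed,
    }
    pair = homogenize_pair(
        train_expr, test_expr, remove_fraction=remove_fraction, apply_eb=apply_eb
    )
    expr, aligned_pheno = align_samples(pair.train, pheno)
    X = expr.values.T
    alpha = {"loo_gcv": "gcv", "cule_deiorio": "cule_deiorio"}[lambda_method]

    if mode == "linear":
        pt = PhenotypePowerTransform(family=transform_family).fit(aligned_pheno.ic50)
        z = pt.transform(aligned_pheno.ic50)
        model = fit_linear_ridge(X, z, ridge_lambda=alpha, alpha_grid=lambda_grid)
        bundle = LinearModelBundle(
            gene_ids=list(expr.gene_ids), model=model, transform=pt
        )
        table = predict_linear(bundle, pair.test)
    else:
        split = binarize_training(
            aligned_pheno, n_sensitive=n_sensitive, n_resistant=n_resistant
        )
        kept = expr.subset_samples(split.sample_ids)
        selection = rank_genes_by_ttest(
            kept.values.T,
            split.labels,
            gene_ids=kept.gene_ids,
            k=k_features,
            variant=ttest_variant,
        )
        X_sel = kept.values.T[:, selection.selected_idx]
        model = fit_logistic_ridge(
            X_sel, split.labels, ridge_lambda="cv", random_state=seed
        )
        bundle = LogisticModelBundle(
            gene_ids=list(selection.selected),
            model=model,
            selection_record=selection,
            class_definition=split,
        )
        table = predict_logistic(bundle, pair.test)

    table.model_provenance = {
        **(table.model_provenance or {}),
        "config_hash": _config_hash(config),
        "seed": seed,
        "n_train": expr.n_samples,
        "n_test": pair.test.n_samples,
        "n_common_genes": len(pair.common_genes),
    }
    logger.info(
        "train_and_predict[%s]: %d train lines, %d patients, %d genes",
        mode, expr.n_samples, pair.test.n_samples, len(pair.common_genes),
    )
    return PipelineResult(
        predictions=table, model=bundle, homogenized=pair, config=config
    )
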