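"""Typed pipeline configuration with validation and lossless round-trip.

Defaults reproduce the method's published operating point: 20% low-variance
gene removal, a 15-sensitive / 55-resistant split for targeted agents,
1,000 t-test-selected features, and 100,000 label permutations for the
empirical AUC p-value.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import numpy as np

__all__ = ["PipelineConfig", "validate_config"]


@dataclass
class PipelineConfig:
    mode: str = "linear"                # linear | logistic
    remove_fraction: float = 0.20       # low-variance gene fraction removed
    apply_eb: bool = True               # empirical-Bayes batch adjustment
    eb_tol: float = 1e-4
    eb_max_iter: int = 100
    transform_family: str = "yeo_johnson"  # yeo_johnson | boxcox_offset
    lambda_method: str = "loo_gcv"      # loo_gcv | cule_deiorio
    lambda_grid_low: float = 1e-3
    lambda_grid_high: float = 1e6
    lambda_grid_size: int = 50
    n_sensitive: int = 15
    n_resistant: int = 55
    k_features: int = 1000
    ttest_variant: str = "pooled"       # feature-selection t statistic
    eval_ttest_variant: str = "welch"   # group-comparison t statistic
    permutations: int = 100_000
    refit_transform: bool = True        # re-estimate transform per LOOCV fold
    summarize: str = "mean"             # duplicate-gene collapse
    seed: int = 0

    def lambda_grid(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.lambda_grid_low),
            np.log10(self.lambda_grid_high),
            self.lambda_grid_size,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> "PipelineConfig":
        checks = [
            (self.mode in ("linear", "logistic"), "mode must be linear|logistic"),
            (0.0 <= self.remove_fraction < 1.0, "remove_fraction must be in [0,1)"),
            (self.eb_tol > 0, "eb_tol must be > 0"),
            (self.eb_max_iter >= 1, "eb_max_iter must be >= 1"),
            (
                self.transform_family in ("yeo_johnson", "boxcox_offset"),
                "transform_family must be yeo_johnson|boxcox_offset",
            ),
            (
                self.lambda_method in ("loo_gcv", "cule_deiorio"),
                "lambda_method must be loo_gcv|cule_deiorio",
            ),
            (
                0 < self.lambda_grid_low <= self.lambda_grid_high,
                "lambda grid bounds must satisfy 0 < low <= high",
            ),
            (self.lambda_grid_size >= 1, "lambda_grid_size must be >= 1"),
            (self.n_sensitive >= 1, "n_sensitive must be >= 1"),
            (self.n_resistant >= 1, "n_resistant must be >= 1"),
            (self.k_features >= 1, "k_features must be >= 1"),
            (
                self.ttest_variant in ("pooled", "welch"),
                "ttest_variant must be pooled|welch",
            ),
            (
                self.eval_ttest_variant in ("pooled", "welch"),
                "eval_ttest_variant must be pooled|welch",
            ),
            (self.permutations >= 1, "permutations must be >= 1"),
            (self.summarize in ("mean", "median"), "summarize must be mean|median"),
            (isinstance(self.seed, int), "seed must be an integer"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")
        return self


def validate_config(raw: dict | None, strict: bool = True) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a raw mapping.

    Missing keys take the published defaults; unknown keys are an error in
    strict mode. The result round-trips losslessly through ``to_dict``.
    """
    raw = dict(raw or {})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        if strict:
            raise ValueError(f"unknown config keys: {unknown}")
        for k in unknown:
            raw.pop(k)
    cfg = PipelineConfig(**raw)
    return cfg.validate()
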