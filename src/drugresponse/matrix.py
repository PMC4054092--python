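"""Core in-memory containers for expression and phenotype data.

An :class:`ExpressionMatrix` is a genes x samples matrix of log2 expression
values; a :class:`PhenotypePanel` holds per-cell-line log IC50 values for one
drug; a :class:`ClinicalResponseTable` carries the clinical endpoint used only
for evaluation (binary responder labels, ordered response categories, or a
continuous phenotype such as months to progression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PhenotypePanel",
    "ClinicalResponseTable",
    "ResponseKind",
    "summarize_duplicate_genes",
    "align_samples",
]


def _as_str_list(x: Sequence[str]) -> list[str]:
    return [str(v) for v in x]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix (log2 scale).

    Duplicate gene identifiers are permitted (they arise before
    :func:`summarize_duplicate_genes`); duplicate sample identifiers are not.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    cohort_label: list[str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_list(self.gene_ids)
        self.sample_ids = _as_str_list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.cohort_label is not None:
            self.cohort_label = _as_str_list(self.cohort_label)
            if len(self.cohort_label) != len(self.sample_ids):
                raise ValueError("cohort_label length must match sample count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            cohort_label=None if self.cohort_label is None else list(self.cohort_label),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, cohort_label: list[str] | None = None
    ) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index.astype(str)),
            sample_ids=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
            cohort_label=cohort_label,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order (gene ids must be unique)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        if len(index) != len(self.gene_ids):
            raise ValueError("subset_genes requires unique gene ids (summarize first)")
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:10]}")
        rows = [index[g] for g in genes]
        return replace(
            self,
            gene_ids=list(genes),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            cohort_label=None if self.cohort_label is None else list(self.cohort_label),
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not present: {missing[:10]}")
        cols = [index[s] for s in samples]
        return replace(
            self,
            gene_ids=list(self.gene_ids),
            sample_ids=list(samples),
            values=self.values[:, cols],
            cohort_label=None
            if self.cohort_label is None
            else [self.cohort_label[c] for c in cols],
        )


@dataclass
class PhenotypePanel:
    """Per-cell-line drug sensitivity (log IC50; lower = more sensitive)."""

    drug_name: str
    sample_ids: list[str]
    ic50: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _as_str_list(self.sample_ids)
        self.ic50 = np.asarray(self.ic50, dtype=float)
        if self.ic50.ndim != 1 or len(self.ic50) != len(self.sample_ids):
            raise ValueError("ic50 must be a vector matching sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in phenotype panel")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def dropna(self) -> "PhenotypePanel":
        keep = np.isfinite(self.ic50)
        return PhenotypePanel(
            drug_name=self.drug_name,
            sample_ids=[s for s, k in zip(self.sample_ids, keep) if k],
            ic50=self.ic50[keep],
        )

    def subset_samples(self, samples: Sequence[str]) -> "PhenotypePanel":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not present: {missing[:10]}")
        return PhenotypePanel(
            drug_name=self.drug_name,
            sample_ids=list(samples),
            ic50=self.ic50[[index[s] for s in samples]],
        )


class ResponseKind(str, Enum):
    BINARY = "binary"
    ORDINAL = "ordinal"
    CONTINUOUS = "continuous"


#: conventional ordering of solid/heme tumor response categories, from best
#: (complete response) to worst (progressive disease)
DEFAULT_ORDINAL_CATEGORIES = ["CR", "PR", "MR", "NC", "PD"]


@dataclass
class ClinicalResponseTable:
    """Clinical endpoint per patient, used only to evaluate predictions."""

    sample_ids: list[str]
    response: np.ndarray
    response_kind: ResponseKind
    categories: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.sample_ids = _as_str_list(self.sample_ids)
        self.response_kind = ResponseKind(self.response_kind)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in response table")
        if self.response_kind is ResponseKind.BINARY:
            self.response = np.asarray(self.response, dtype=int)
            if not set(np.unique(self.response)) <= {0, 1}:
                raise ValueError("binary response must be coded 0/1")
        elif self.response_kind is ResponseKind.ORDINAL:
            self.response = np.asarray(self.response, dtype=object)
            if self.categories is None:
                raise ValueError("ordinal response requires an explicit category order")
            unknown = sorted(set(map(str, self.response)) - set(self.categories))
            if unknown:
                raise ValueError(f"response categories not in declared order: {unknown}")
        else:
            self.response = np.asarray(self.response, dtype=float)
        if len(self.response) != len(self.sample_ids):
            raise ValueError("response length must match sample_ids")


def summarize_duplicate_genes(
    matrix: ExpressionMatrix, how: str = "mean"
) -> ExpressionMatrix:
    """Collapse rows sharing a gene symbol to their element-wise mean.

    Probes mapping to the same symbol are averaged on the log2 scale
    (``how="median"`` is available as a non-default alternative). Surviving
    gene order is first-occurrence order; the sample axis is untouched.
    Idempotent: matrices with unique gene ids pass through unchanged.
    """
    if how not in ("mean", "median"):
        raise ValueError("how must be 'mean' or 'median'")
    order: dict[str, int] = {}
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(matrix.gene_ids):
        if g not in order:
            order[g] = len(order)
            groups[g] = []
        groups[g].append(i)
    if len(order) == matrix.n_genes:
        return matrix.copy()
    agg = np.mean if how == "mean" else np.median
    out = np.empty((len(order), matrix.n_samples), dtype=float)
    genes = sorted(order, key=order.__getitem__)
    for j, g in enumerate(genes):
        rows = groups[g]
        out[j] = matrix.values[rows[0]] if len(rows) == 1 else agg(
            matrix.values[rows], axis=0
        )
    return ExpressionMatrix(
        gene_ids=genes,
        sample_ids=list(matrix.sample_ids),
        values=out,
        cohort_label=None if matrix.cohort_label is None else list(matrix.cohort_label),
    )


def align_samples(
    expr: ExpressionMatrix, pheno: PhenotypePanel
) -> tuple[ExpressionMatrix, PhenotypePanel]:
    """Restrict both inputs to samples with expression and a measured IC50.

    Keeps the expression matrix's column order; samples with a missing IC50
    are excluded. Errors if the intersection is empty.
    """
    measured = {
        s for s, v in zip(pheno.sample_ids, pheno.ic50) if np.isfinite(v)
    }
    common = [s for s in expr.sample_ids if s in measured]
    if not common:
        raise ValueError(
            "no samples with both expression and a measured IC50 "
            f"(expression n={expr.n_samples}, phenotype n={pheno.n_samples})"
        )
    logger.info(
        "align_samples: %d/%d expression samples have a measured IC50 for %s",
        len(common), expr.n_samples, pheno.drug_name,
    )
    return expr.subset_samples(common), pheno.subset_samples(common)
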