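"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices travel as genes-x-samples TSV (header row of sample ids,
first column of gene symbols) or GCT 1.2; phenotype and clinical-response
tables as small two/three-column TSVs. All numeric output is written with six
significant digits.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import (
    ClinicalResponseTable,
    ExpressionMatrix,
    PhenotypePanel,
    ResponseKind,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "read_response",
    "write_predictions",
]

FLOAT_FMT = "%.6g"


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "gct"):
            raise ValueError(f"unknown expression format {fmt!r}")
        return fmt
    return "gct" if str(path).lower().endswith(".gct") else "tsv"


def _parse_body(
    lines: list[str], path: str | Path, n_id_cols: int
) -> ExpressionMatrix:
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[n_id_cols:]
    if not sample_ids:
        raise ValueError(f"{path}: no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        genes.append(parts[0])
        row = []
        for sample, cell in zip(sample_ids, parts[n_id_cols:]):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {cell!r} "
                    f"(gene {parts[0]!r}, sample {sample!r})"
                ) from None
        rows.append(row)
    if not genes:
        raise ValueError(f"{path}: empty expression matrix")
    return ExpressionMatrix(
        gene_ids=genes, sample_ids=sample_ids, values=np.array(rows, dtype=float)
    )


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from TSV or GCT 1.2."""
    fmt = _infer_format(path, format)
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if fmt == "tsv":
        return _parse_body(lines, path, n_id_cols=1)
    if len(lines) < 3 or not lines[0].startswith("#1.2"):
        raise ValueError(f"{path}: not a GCT 1.2 file (missing '#1.2' header)")
    try:
        n_genes, n_samples = (int(x) for x in lines[1].split("\t")[:2])
    except ValueError:
        raise ValueError(f"{path}: malformed GCT dimensions line") from None
    matrix = _parse_body(lines[2:], path, n_id_cols=2)
    if matrix.n_genes != n_genes or matrix.n_samples != n_samples:
        raise ValueError(
            f"{path}: GCT dimensions line says {n_genes}x{n_samples}, "
            f"body is {matrix.n_genes}x{matrix.n_samples}"
        )
    return matrix


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, format: str | None = None
) -> None:
    """Write an expression matrix as TSV or GCT 1.2 (6 significant digits)."""
    if matrix.n_samples == 0 or matrix.n_genes == 0:
        raise ValueError("refusing to write an empty expression matrix")
    fmt = _infer_format(path, format)
    buf = _io.StringIO()
    if fmt == "gct":
        buf.write("#1.2\n")
        buf.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        buf.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            buf.write(g + "\t" + g + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")
    else:
        buf.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            buf.write(g + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_phenotype(path: str | Path, drug_name: str | None = None) -> PhenotypePanel:
    """Read a two-column (sample id, log IC50) TSV with a header row.

    The drug name defaults to the header of the second column. Blank or "NA"
    IC50 cells become missing values, not zeros.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty phenotype file") from None
        if len(header) < 2:
            raise ValueError(f"{path}: need two columns (sample id, log IC50)")
        samples: list[str] = []
        ic50: list[float] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: need two columns")
            samples.append(row[0])
            cell = row[1].strip()
            if cell in ("", "NA", "NaN", "nan"):
                ic50.append(np.nan)
            else:
                try:
                    ic50.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric IC50 {cell!r}"
                    ) from None
    if not samples:
        raise ValueError(f"{path}: no phenotype rows")
    return PhenotypePanel(
        drug_name=drug_name if drug_name is not None else header[1],
        sample_ids=samples,
        ic50=np.array(ic50, dtype=float),
    )


def write_phenotype(panel: PhenotypePanel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"sample_id\t{panel.drug_name}\n")
        for s, v in zip(panel.sample_ids, panel.ic50):
            fh.write(f"{s}\t{'NA' if not np.isfinite(v) else FLOAT_FMT % v}\n")


def read_response(
    path: str | Path,
    response_kind: str | ResponseKind,
    categories: list[str] | None = None,
) -> ClinicalResponseTable:
    """Read a two-column (sample id, response) TSV with a header row."""
    kind = ResponseKind(response_kind)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need two columns (sample id, response)")
    samples = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1]
    if kind is ResponseKind.BINARY:
        response = raw.astype(int).to_numpy()
    elif kind is ResponseKind.CONTINUOUS:
        response = raw.astype(float).to_numpy()
    else:
        response = raw.astype(str).to_numpy()
    return ClinicalResponseTable(
        sample_ids=samples, response=response, response_kind=kind,
        categories=categories,
    )


def write_predictions(table, path: str | Path) -> None:
    """Write a PredictionTable as TSV (sample_id, predicted[, probability])."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["sample_id", "predicted"]
        has_prob = table.probability is not None
        if has_prob:
            cols.append("probability")
        fh.write("\t".join(cols) + "\n")
        for i, s in enumerate(table.sample_ids):
            row = [s, FLOAT_FMT % table.predicted[i]]
            if has_prob:
                row.append(FLOAT_FMT % table.probability[i])
            fh.write("\t".join(row) + "\n")
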