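"""Expression-matrix, annotation, clinical and signature-table I/O.

The universal in-memory container is :class:`ExpressionMatrix`, a thin
validated wrapper around a genes x samples :class:`pandas.DataFrame`.
All downstream operations are rank-based within each sample, so the
absolute scale only matters for the preprocessing steps here (probe
averaging happens on the incoming scale; zero filtering assumes a
linear FPKM/count scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_map",
    "collapse_probes",
    "filter_rnaseq_zeros",
    "intersect_genes",
    "read_clinical_table",
    "write_clinical_table",
    "GRADE_LABELS",
]

#: Recognized pathological grade labels; anything else becomes "unknown".
GRADE_LABELS = ("pHG1", "pHG2", "pHG3", "unknown")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with unique row/column IDs.

    Parameters
    ----------
    data:
        DataFrame indexed by gene (or probe) ID with sample-ID columns.
        Values are floats; NaN marks a missing measurement.
    scale:
        ``"log2"`` for log2-scale microarray intensities, ``"linear"``
        for FPKM/count-like values.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise ValueError(f"duplicate gene IDs: {dups[:10]}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise ValueError(f"duplicate sample IDs: {dups[:10]}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if np.isinf(vals).any():
            raise ValueError("expression values must be finite or NaN")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.scale)


def read_expression_matrix(
    path: str | Path, delimiter: str = "\t", scale: str = "log2"
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    Layout: header row of sample IDs, first column of gene IDs, "." as
    the decimal mark. Duplicate gene rows are an error here — probe
    collapsing must go through :func:`collapse_probes` so the averaging
    rule is explicit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"cannot parse expression matrix {path}: empty file")
    sample_ids = header.rstrip("\n").split(delimiter)[1:]
    if len(sample_ids) != len(set(sample_ids)):
        seen: set[str] = set()
        dups = []
        for s in sample_ids:
            if s in seen:
                dups.append(s)
            seen.add(s)
        raise ValueError(f"duplicate sample IDs in {path}: {sorted(set(dups))}")
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"cannot parse expression matrix {path}: empty file") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ValueError(
            f"duplicate gene ID rows in {path}: {dups[:10]} "
            "(collapse probes with collapse_probes before loading as genes)"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad_mask = numeric.isna().to_numpy() & df.notna().to_numpy()
    if bad_mask.any():
        i, j = np.argwhere(bad_mask)[0]
        raise ValueError(
            f"non-numeric value {df.iat[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r} in {path}"
        )
    return ExpressionMatrix(numeric, scale=scale)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    matrix.data.to_csv(path, sep=delimiter, index_label="gene_id")


def read_probe_map(path: str | Path, delimiter: str = "\t") -> dict[str, set[str]]:
    """Read a two-column (probe_id, gene_id) mapping table.

    A probe listed on several rows is multi-mapped. A header line with
    the literal column names is tolerated and skipped.
    """
    probe_map: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if lineno == 0 and fields[:2] == ["probe_id", "gene_id"]:
                continue
            if len(fields) < 2:
                raise ValueError(f"probe map line {lineno + 1} has fewer than 2 columns")
            probe, gene = fields[0], fields[1]
            probe_map.setdefault(probe, set())
            if gene:
                probe_map[probe].add(gene)
    return probe_map


def collapse_probes(
    matrix: ExpressionMatrix, probe_map: Mapping[str, Iterable[str]]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to genes.

    Probes mapping to zero genes or to more than one gene are dropped;
    the remaining probes are grouped by gene and averaged per sample on
    the incoming scale (log2 in, log2-mean out). Missing probe values
    are excluded from the mean; a gene-sample cell with no contributing
    measurement is missing.
    """
    gene_of: dict[str, str] = {}
    for probe in matrix.gene_ids:
        genes = set(probe_map.get(probe, ()))
        if len(genes) == 1:
            gene_of[probe] = next(iter(genes))
    if not gene_of:
        raise ValueError("no probe maps uniquely to a gene; nothing to collapse")
    kept = matrix.data.loc[list(gene_of)]
    grouped = kept.groupby(by=[gene_of[p] for p in kept.index]).mean()
    grouped = grouped.sort_index()
    return ExpressionMatrix(grouped, scale=matrix.scale)


def filter_rnaseq_zeros(
    matrix: ExpressionMatrix, max_zero_fraction: float = 0.75
) -> ExpressionMatrix:
    """Filter zero-heavy genes and fill residual zeros (RNA-seq rule).

    Genes with zeros in strictly more than ``max_zero_fraction`` of
    samples are removed; every remaining zero is replaced by the
    smallest positive value of the post-filter matrix, so no zeros
    survive and within-sample rankings are well defined on a linear
    scale.
    """
    if matrix.scale != "linear":
        raise ValueError("zero filtering applies to linear-scale (FPKM/count) matrices")
    vals = matrix.data.to_numpy()
    if np.nanmin(vals) < 0:
        raise ValueError("linear-scale matrix must be non-negative")
    zero_frac = (vals == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    kept = matrix.data.loc[keep]
    kvals = kept.to_numpy()
    positive = kvals[np.isfinite(kvals) & (kvals > 0)]
    if positive.size == 0:
        raise ValueError("no positive value remains after zero filtering; cannot fill zeros")
    fill = float(positive.min())
    filled = kept.where(kept != 0, other=fill)
    return ExpressionMatrix(filled, scale="linear")


def intersect_genes(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the common gene set, rows sorted identically.

    This is the cross-platform harmonization step: downstream discovery
    compares orderings of the same genes across cohorts measured on
    different platforms.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    common: set[str] = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("gene-ID intersection across matrices is empty")
    order = sorted(common)
    return [ExpressionMatrix(m.data.loc[order], m.scale) for m in matrices]


def read_clinical_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a clinical table: sample_id, grade, time, event (header required).

    Returns a DataFrame indexed by sample_id with columns ``grade``
    (one of pHG1/pHG2/pHG3/unknown), ``time`` (>= 0) and ``event``
    (0 censored / 1 relapse-or-death, per the chosen endpoint).
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str})
    required = {"sample_id", "grade", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs in clinical table: {dups[:10]}")
    df = df.set_index("sample_id")
    df["grade"] = [g if g in GRADE_LABELS else "unknown" for g in df["grade"].astype(str)]
    df["time"] = pd.to_numeric(df["time"])
    df["event"] = pd.to_numeric(df["event"]).astype(int)
    if (df["time"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return df


def write_clinical_table(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")
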