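"""Cluster-level marker-gene tables and the expression-proportion matrix.

The pipeline consumes the long-format differential-expression table that
Seurat's ``FindAllMarkers`` emits (one row per marker gene per cluster),
applies the adjusted-p-value screen, pivots it into a dense gene × cluster
matrix ``A``, and normalizes each gene's row to proportions ``E`` (each
entry divided by the gene's total across clusters).  ``E`` is what the
similarity scoring consumes: it measures where, across clusters, a marker
gene's signal concentrates.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from .dictionary import normalize_gene
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: FindAllMarkers value-column aliases, in preference order.
VALUE_COLUMN_ALIASES = {"avg_log2FC": ("avg_log2FC", "avg_logFC")}


@dataclass
class MarkerTable:
    """Filtered long-format marker table with one row per (gene, cluster).

    Attributes
    ----------
    data:
        Columns ``gene``, ``cluster``, ``value`` plus any auxiliary columns
        preserved from the input.
    n_clipped:
        Number of negative values clipped to zero during loading.
    """

    data: pd.DataFrame
    n_clipped: int = 0

    def __post_init__(self) -> None:
        missing = {"gene", "cluster", "value"} - set(self.data.columns)
        if missing:
            raise SchemaError(f"marker table missing columns: {sorted(missing)}")
        if self.data.duplicated(subset=["gene", "cluster"]).any():
            raise ValidationError("duplicate (gene, cluster) rows in marker table")
        if (self.data["value"] < 0).any():
            raise ValidationError("marker table values must be nonnegative")


@dataclass
class ExpressionMatrix:
    """Gene × cluster expression matrix ``A`` and its proportion matrix ``E``.

    ``E`` rows for genes with nonzero total sum to one; all-zero rows stay
    all-zero.  ``E`` is ``None`` until :func:`normalize_expression` runs.
    """

    A: pd.DataFrame
    E: pd.DataFrame | None = field(default=None)

    @property
    def genes(self) -> list[str]:
        return list(self.A.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.A.columns)


def _sep_for(path, sep: str | None) -> str:
    if sep is not None:
        return sep
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def read_marker_table(
    path,
    value_column: str = "avg_log2FC",
    p_adj_threshold: float = 0.05,
    *,
    sep: str | None = None,
    case_fold: bool = True,
    on_duplicate: str = "error",
) -> MarkerTable:
    """Load a FindAllMarkers-style table and apply the significance screen.

    Rows with adjusted p-value at or above ``p_adj_threshold`` are dropped
    (the filter is skipped, with a warning, when no ``p_val_adj`` column is
    present).  Negative values are clipped to zero and counted.  Duplicate
    (gene, cluster) pairs are an error by default; ``on_duplicate="max"``
    keeps the largest value instead.

    Parameters
    ----------
    value_column:
        Which column feeds the expression matrix; default ``avg_log2FC``
        (``avg_logFC`` accepted as an alias).
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    cols = {c.lower(): c for c in df.columns}
    for req in ("gene", "cluster"):
        if req not in cols:
            raise SchemaError(f"marker table {path} lacks a '{req}' column")
    vcol = None
    for cand in VALUE_COLUMN_ALIASES.get(value_column, (value_column,)):
        if cand.lower() in cols:
            vcol = cols[cand.lower()]
            break
    if vcol is None:
        raise SchemaError(
            f"value column '{value_column}' not found in {path}; "
            f"available columns: {list(df.columns)}"
        )
    if "p_val_adj" in cols:
        padj = pd.to_numeric(df[cols["p_val_adj"]], errors="coerce")
        df = df[(padj < p_adj_threshold) | padj.isna()]
    else:
        logger.warning("no p_val_adj column in %s; significance filter skipped", path)

    out = df.rename(columns={cols["gene"]: "gene", cols["cluster"]: "cluster"}).copy()
    out["gene"] = out["gene"].map(lambda g: normalize_gene(g, case_fold))
    out["cluster"] = out["cluster"].astype(str).str.strip()
    value = pd.to_numeric(out[vcol], errors="coerce").fillna(0.0)
    n_clipped = int((value < 0).sum())
    if n_clipped:
        logger.warning("clipped %d negative value(s) to 0", n_clipped)
    out["value"] = value.clip(lower=0.0)

    dup = out.duplicated(subset=["gene", "cluster"], keep=False)
    if dup.any():
        if on_duplicate == "max":
            out = (
                out.sort_values("value", kind="mergesort")
                .drop_duplicates(subset=["gene", "cluster"], keep="last")
                .sort_index()
            )
        else:
            pair = out.loc[dup, ["gene", "cluster"]].iloc[0]
            raise ValidationError(
                f"duplicate (gene, cluster) rows in {path}, e.g. "
                f"({pair['gene']}, {pair['cluster']})"
            )
    aux = [c for c in out.columns if c not in ("gene", "cluster", "value", vcol)]
    return MarkerTable(out[["gene", "cluster", "value", *aux]].reset_index(drop=True),
                       n_clipped=n_clipped)


def build_expression_matrix(table: MarkerTable) -> ExpressionMatrix:
    """Pivot the long marker table into a dense gene × cluster matrix.

    Unobserved (gene, cluster) cells become 0 — the upstream marker caller
    only reports detected markers, so absence is treated as no evidence.
    Row/column order is first appearance in the table.
    """
    df = table.data
    if not len(df):
        raise ValidationError("cannot build an expression matrix from an empty table")
    genes = list(dict.fromkeys(df["gene"]))
    clusters = list(dict.fromkeys(df["cluster"]))
    A = (
        df.pivot_table(index="gene", columns="cluster", values="value",
                       aggfunc="sum", fill_value=0.0)
        .reindex(index=genes, columns=clusters)
        .astype(float)
    )
    return ExpressionMatrix(A=A)


def normalize_expression(matrix: ExpressionMatrix, axis: str = "gene") -> ExpressionMatrix:
    """Compute the proportion matrix ``E`` from ``A``.

    ``axis="gene"`` (default) divides each entry by its gene's total across
    clusters; ``axis="cluster"`` divides by the cluster's total across
    genes, offered for sensitivity checks.  Zero-sum rows (or columns) stay
    zero.  ``A`` is left untouched.
    """
    if axis not in ("gene", "cluster"):
        raise ValueError(f"axis must be 'gene' or 'cluster', got {axis!r}")
    A = matrix.A
    if axis == "gene":
        totals = A.sum(axis=1)
        E = A.div(totals.where(totals > 0, 1.0), axis=0)
    else:
        totals = A.sum(axis=0)
        E = A.div(totals.where(totals > 0, 1.0), axis=1)
    return ExpressionMatrix(A=A, E=E)


def write_matrix(matrix: pd.DataFrame, path, *, index_label: str = "gene") -> None:
    """Write a genes-as-rows matrix as TSV."""
    matrix.to_csv(path, sep="\t", index_label=index_label)
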