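"""Cell-type → marker-gene voting dictionary.

The dictionary records, for each (cell type, marker gene) pair, how many
curated literature sources vote for that gene as a marker of that type.  A
gene's weight within a cell type is its vote count divided by the type's
total votes, so per-type weights sum to one.  Weighted marker dictionaries
of this shape drive the cluster-similarity scoring in
:mod:`fpcam.annotation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical dictionary TSV columns and their accepted aliases (matched
#: case-insensitively after collapsing spaces/underscores).
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "cell_cluster": ("cell_cluster", "cell cluster", "cell_type", "cell type"),
    "marker_gene": ("marker_gene", "marker gene", "gene"),
    "n_votes": ("n_votes", "number of votes received", "votes_received"),
    "votes_total": ("votes_total", "votes", "total_votes"),
    "percent": ("percent", "fraction", "weight"),
}

_REQUIRED = ("cell_cluster", "marker_gene", "n_votes", "votes_total")


def normalize_gene(symbol: str, case_fold: bool = True) -> str:
    """Trim whitespace and (by default) upper-case a gene symbol.

    Case folding reconciles human (TP63) and mouse (Tp63) symbol
    conventions mixed across literature sources.
    """
    s = str(symbol).strip()
    return s.upper() if case_fold else s


def _canonical_header(columns: Iterable[str]) -> dict[str, str]:
    """Map canonical column names to the actual header names in *columns*."""
    def squash(name: str) -> str:
        return " ".join(str(name).replace("_", " ").lower().split())

    lookup = {squash(c): c for c in columns}
    found: dict[str, str] = {}
    for canon, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if squash(alias) in lookup:
                found[canon] = lookup[squash(alias)]
                break
    return found


@dataclass(frozen=True)
class VoteRecord:
    """One (cell type, gene) voting entry of the dictionary."""

    cell_type: str
    gene: str
    votes: int
    total_votes: int

    def __post_init__(self) -> None:
        if self.votes < 0:
            raise ValidationError(f"votes must be nonnegative, got {self.votes}")
        if self.total_votes <= 0:
            raise ValidationError(
                f"total_votes must be positive, got {self.total_votes}"
            )
        if self.votes > self.total_votes:
            raise ValidationError(
                f"votes ({self.votes}) exceed total_votes ({self.total_votes}) "
                f"for ({self.cell_type}, {self.gene})"
            )

    @property
    def percent(self) -> Fraction:
        """Exact voting ratio votes / total_votes."""
        return Fraction(self.votes, self.total_votes)


@dataclass
class MarkerDictionary:
    """A validated voting dictionary with derived per-type gene weights.

    Parameters
    ----------
    data:
        One row per (cell_type, gene) with integer ``votes`` and
        ``total_votes`` columns.  Construction deduplicates pairs,
        reconciles totals and computes weights.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cell_type", "gene", "votes", "total_votes"]))

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"cell_type", "gene", "votes", "total_votes"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"dictionary frame missing columns: {sorted(missing)}")
        if len(df):
            dup = df.duplicated(subset=["cell_type", "gene"])
            if dup.any():
                logger.warning(
                    "summing %d duplicate (cell_type, gene) rows", int(dup.sum())
                )
                df = (
                    df.groupby(["cell_type", "gene"], sort=False, as_index=False)
                    .agg(votes=("votes", "sum"), total_votes=("total_votes", "max"))
                )
            # totals must equal the per-type vote sum for weights to normalize
            sums = df.groupby("cell_type", sort=False)["votes"].transform("sum")
            stated = df["total_votes"]
            if (stated != sums).any():
                bad = df.loc[stated != sums, "cell_type"].unique()
                logger.warning(
                    "total_votes reconciled to per-type vote sums for %d cell "
                    "type(s): %s", len(bad), ", ".join(map(str, bad[:5])),
                )
            df["total_votes"] = sums
            if (df["total_votes"] <= 0).any():
                zero = df.loc[df["total_votes"] <= 0, "cell_type"].unique()
                raise ValidationError(
                    f"cell type(s) with zero total votes: {', '.join(map(str, zero))}"
                )
            df["weight"] = df["votes"] / df["total_votes"]
        else:
            df["weight"] = pd.Series(dtype=float)
        self.data = df.reset_index(drop=True)

    # -- views ------------------------------------------------------------
    @property
    def cell_types(self) -> list[str]:
        """Unique cell types in first-appearance order."""
        return list(dict.fromkeys(self.data["cell_type"]))

    @property
    def genes(self) -> list[str]:
        """Unique gene symbols in first-appearance order."""
        return list(dict.fromkeys(self.data["gene"]))

    @property
    def records(self) -> list[VoteRecord]:
        return [
            VoteRecord(r.cell_type, r.gene, int(r.votes), int(r.total_votes))
            for r in self.data.itertuples(index=False)
        ]

    @property
    def weights(self) -> dict[tuple[str, str], float]:
        """Mapping (cell_type, gene) → vote weight in (0, 1]."""
        return {
            (r.cell_type, r.gene): float(r.weight)
            for r in self.data.itertuples(index=False)
        }

    def weight_matrix(self) -> pd.DataFrame:
        """Dense gene × cell-type weight matrix (zeros where no record)."""
        if not len(self.data):
            return pd.DataFrame(dtype=float)
        return (
            self.data.pivot_table(
                index="gene", columns="cell_type", values="weight",
                aggfunc="sum", fill_value=0.0,
            )
            .reindex(index=self.genes, columns=self.cell_types)
            .astype(float)
        )

    def percent_of(self, cell_type: str, gene: str) -> Fraction:
        """Exact voting ratio of one record."""
        row = self.data[
            (self.data["cell_type"] == cell_type) & (self.data["gene"] == gene)
        ]
        if not len(row):
            raise KeyError((cell_type, gene))
        r = row.iloc[0]
        return Fraction(int(r["votes"]), int(r["total_votes"]))

    def genes_of(self, cell_type: str) -> list[str]:
        return list(self.data.loc[self.data["cell_type"] == cell_type, "gene"])


def compute_weights(dictionary: MarkerDictionary) -> MarkerDictionary:
    """Recompute per-type gene weights as votes / Σ votes over the type.

    Weights are derived automatically during construction; this re-derives
    them (returning a fresh dictionary) for records whose vote counts were
    mutated.
    """
    return MarkerDictionary(dictionary.data[["cell_type", "gene", "votes",
                                             "total_votes"]])


def _parse_percent(text: object) -> float | None:
    s = str(text).strip()
    if not s or s.lower() == "nan":
        return None
    if "/" in s:
        num, _, den = s.partition("/")
        try:
            return int(num) / int(den)
        except (ValueError, ZeroDivisionError):
            return None
    try:
        return float(s)
    except ValueError:
        return None


def read_dictionary(path, *, case_fold: bool = True) -> MarkerDictionary:
    """Read a five-column dictionary TSV into a :class:`MarkerDictionary`.

    Accepts the canonical header (``cell_cluster``, ``marker_gene``,
    ``n_votes``, ``votes_total``, ``percent``) or its published aliases,
    case-insensitively.  Duplicate (cell type, gene) rows are summed; the
    ``percent`` column, when parseable, is checked against votes/total and
    a mismatch is logged, never trusted.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    header = _canonical_header(raw.columns)
    missing = [c for c in _REQUIRED if c not in header]
    if missing:
        raise SchemaError(
            f"dictionary file {path} is missing required column(s): "
            f"{', '.join(missing)}"
        )
    df = pd.DataFrame({
        "cell_type": raw[header["cell_cluster"]].astype(str).str.strip(),
        "gene": raw[header["marker_gene"]].map(
            lambda g: normalize_gene(g, case_fold)),
    })
    for canon, out in (("n_votes", "votes"), ("votes_total", "total_votes")):
        col = pd.to_numeric(raw[header[canon]], errors="coerce")
        bad = col.isna() | (col != col.round())
        if bad.any():
            rownum = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValidationError(
                f"non-integer value in column '{header[canon]}' at line {rownum}"
            )
        df[out] = col.astype(int)
    over = df["votes"] > df["total_votes"]
    if over.any():
        rownum = int(np.flatnonzero(over.to_numpy())[0]) + 2
        raise ValidationError(
            f"votes exceed total_votes at line {rownum} of {path}"
        )
    if "percent" in header:
        stated = raw[header["percent"]].map(_parse_percent)
        with np.errstate(invalid="ignore"):
            expect = df["votes"] / df["total_votes"]
        mism = stated.notna() & (abs(stated - expect) > 1e-6)
        if mism.any():
            logger.warning(
                "%d percent value(s) disagree with votes/total; recomputed",
                int(mism.sum()),
            )
    return MarkerDictionary(df)


def write_dictionary(dictionary: MarkerDictionary, path) -> None:
    """Write the five-column dictionary TSV with percent as a reduced fraction.

    Round-trips losslessly through :func:`read_dictionary`.
    """
    df = dictionary.data
    out = pd.DataFrame({
        "cell_cluster": df["cell_type"],
        "marker_gene": df["gene"],
        "n_votes": df["votes"],
        "votes_total": df["total_votes"],
        "percent": [
            str(Fraction(int(v), int(t)))
            for v, t in zip(df["votes"], df["total_votes"])
        ],
    })
    out.to_csv(path, sep="\t", index=False)


def build_votes_from_sources(
    source_tables: Sequence[pd.DataFrame],
    *,
    top_n: int = 10,
    case_fold: bool = True,
) -> MarkerDictionary:
    """Tally per-study marker lists into a voting dictionary.

    Each source table needs ``cell_type`` and ``gene`` columns and may carry
    a ``rank`` column (1 = most important; defaults to appearance order
    within each source × type).  A gene's votes for a type is the number of
    sources listing it; only the ``top_n`` genes per type are retained,
    ranked by votes (descending), then by the best rank the gene achieved
    in any source, then by gene symbol.
    """
    if not len(source_tables):
        raise ValidationError("at least one source table is required")
    rows = []
    for k, src in enumerate(source_tables):
        cols = {c.lower(): c for c in src.columns}
        if "cell_type" not in cols or "gene" not in cols:
            raise SchemaError(
                f"source table {k} lacks a cell_type/gene column "
                f"(found: {list(src.columns)})"
            )
        t = pd.DataFrame({
            "cell_type": src[cols["cell_type"]].astype(str).str.strip(),
            "gene": src[cols["gene"]].map(lambda g: normalize_gene(g, case_fold)),
        })
        if "rank" in cols:
            t["rank"] = pd.to_numeric(src[cols["rank"]], errors="coerce")
        else:
            t["rank"] = t.groupby("cell_type").cumcount() + 1
        # one vote per source even if a source repeats a gene
        t = t.drop_duplicates(subset=["cell_type", "gene"])
        t["source"] = k
        rows.append(t)
    long = pd.concat(rows, ignore_index=True)
    tally = (
        long.groupby(["cell_type", "gene"], sort=False)
        .agg(votes=("source", "nunique"), best_rank=("rank", "min"))
        .reset_index()
    )
    kept = []
    for cell_type, grp in tally.groupby("cell_type", sort=False):
        grp = grp.sort_values(
            by=["votes", "best_rank", "gene"], ascending=[False, True, True],
            kind="mergesort",
        ).head(top_n)
        total = int(grp["votes"].sum())
        kept.append(grp.assign(total_votes=total))
    out = pd.concat(kept, ignore_index=True)
    return MarkerDictionary(out[["cell_type", "gene", "votes", "total_votes"]])


def dictionary_stats(dictionary: MarkerDictionary) -> dict:
    """Summary counts: unique genes/types, records, genes per type."""
    df = dictionary.data
    per_type = df.groupby("cell_type", sort=False)["gene"].nunique().to_dict()
    return {
        "n_genes": int(df["gene"].nunique()),
        "n_cell_types": int(df["cell_type"].nunique()),
        "n_records": int(len(df)),
        "genes_per_type": per_type,
    }
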