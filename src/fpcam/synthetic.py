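"""Synthetic dictionaries, marker tables, and annotator panels.

Planted-ground-truth generators for every pipeline stage: a voting
dictionary whose per-type marker sets are known, a cluster-level marker
table in the FindAllMarkers column convention whose clusters were assigned
known cell types, and a panel of annotators with controlled error rates.
The generator is a first-class, deterministic simulation tool: every
operation consumes an explicit seed through ``SyntheticSpec``.

What it emulates: the long-format marker-caller output (values per gene per
cluster, adjusted p-values below the screen), a literature voting profile
over 1..n_sources, partially shared marker sets between related types
(``marker_overlap``), multiplicative log-normal measurement noise and
marker dropout.  What it does not emulate: per-cell counts, library-size
effects, batch structure, or correlated errors between annotators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dictionary import MarkerDictionary
from .errors import ValidationError
from .evaluation import LabelTable
from .expression import MarkerTable

#: Vote profile of the worked basal-resting example (sums to 21 over 10 genes).
TABLE2_VOTE_PROFILE = (4, 4, 3, 2, 2, 2, 1, 1, 1, 1)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``marker_overlap`` is the fraction of each type's genes shared with the
    previous (adjacent) type; ``noise_sd`` the σ of multiplicative
    log-normal noise on expression values; ``dropout`` the probability a
    true marker row is omitted from the marker table.
    """

    n_cell_types: int = 8
    n_clusters: int = 8
    genes_per_type: int = 10
    n_sources: int = 6
    marker_overlap: float = 0.0
    noise_sd: float = 0.0
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2:
            raise ValidationError("n_cell_types must be at least 2")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be at least 1")
        if self.genes_per_type < 1:
            raise ValidationError("genes_per_type must be at least 1")
        if self.n_sources < 1:
            raise ValidationError("n_sources must be at least 1")
        if not 0 <= self.marker_overlap < 1:
            raise ValidationError("marker_overlap must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must lie in [0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one sub-operation of this spec."""
        return np.random.default_rng([self.seed, stream])

    def replace(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)


#: Small default study for quick runs.
SMALL_PRESET = SyntheticSpec(n_cell_types=6, n_clusters=6)

#: Study at the scale of a curated lung dictionary and clustered dataset:
#: 75 cell subtypes, 10 markers each with partial sharing between related
#: types, 29 clusters, 6 literature sources.
PAPER_PRESET = SyntheticSpec(
    n_cell_types=75,
    n_clusters=29,
    genes_per_type=10,
    n_sources=6,
    marker_overlap=0.2,
    noise_sd=0.3,
    dropout=0.05,
)

PRESETS = {"small": SMALL_PRESET, "paper": PAPER_PRESET}


def _type_name(i: int) -> str:
    return f"Type_{i:03d}"


def make_dictionary(
    spec: SyntheticSpec,
    vote_profile: tuple[int, ...] | None = None,
) -> tuple[MarkerDictionary, dict[str, list[str]]]:
    """Generate a voting dictionary with known per-type marker sets.

    Adjacent types share ``ceil(marker_overlap × genes_per_type)`` genes
    (type k reuses the tail of type k−1's genes).  Vote counts are drawn
    uniformly from 1..n_sources unless a fixed ``vote_profile`` of length
    ``genes_per_type`` is supplied.

    Returns the dictionary and the planted type → gene-list map.
    """
    n_shared = math.ceil(spec.marker_overlap * spec.genes_per_type)
    if n_shared >= spec.genes_per_type:
        raise ValidationError(
            "marker_overlap so high that adjacent types would share every gene"
        )
    if vote_profile is not None and len(vote_profile) != spec.genes_per_type:
        raise ValidationError("vote_profile length must equal genes_per_type")
    rng = spec.rng(stream=1)
    truth: dict[str, list[str]] = {}
    rows = []
    next_gene = 0
    prev_genes: list[str] = []
    for t in range(spec.n_cell_types):
        cell_type = _type_name(t)
        shared = prev_genes[-n_shared:] if (n_shared and t > 0) else []
        fresh = [f"GENE{next_gene + k:05d}"
                 for k in range(spec.genes_per_type - len(shared))]
        next_gene += len(fresh)
        genes = shared + fresh
        if vote_profile is not None:
            votes = list(vote_profile)
        else:
            votes = rng.integers(1, spec.n_sources + 1,
                                 size=spec.genes_per_type).tolist()
        total = int(sum(votes))
        for g, v in zip(genes, votes):
            rows.append((cell_type, g, int(v), total))
        truth[cell_type] = genes
        prev_genes = genes
    df = pd.DataFrame(rows, columns=["cell_type", "gene", "votes", "total_votes"])
    return MarkerDictionary(df), truth


def default_assignment(spec: SyntheticSpec) -> dict[str, str]:
    """Deterministic cluster → type map cycling through the types."""
    return {
        str(c): _type_name(c % spec.n_cell_types) for c in range(spec.n_clusters)
    }


def random_assignment(spec: SyntheticSpec) -> dict[str, str]:
    """Uniformly random cluster → type map (seeded by the spec)."""
    rng = spec.rng(stream=2)
    picks = rng.integers(0, spec.n_cell_types, size=spec.n_clusters)
    return {str(c): _type_name(int(t)) for c, t in enumerate(picks)}


def make_marker_table(
    spec: SyntheticSpec,
    dictionary: MarkerDictionary,
    assignment: dict[str, str],
) -> MarkerTable:
    """Emit a FindAllMarkers-convention marker table for planted clusters.

    Each cluster's rows are its assigned type's marker genes with values
    proportional to the dictionary weights, perturbed by log-normal noise
    of σ ``noise_sd`` and thinned with probability ``dropout``; adjusted
    p-values are drawn strictly below the default 0.05 screen so true rows
    survive loading.
    """
    missing = [str(c) for c in assignment if assignment[str(c)] not in
               set(dictionary.cell_types)]
    if missing:
        raise ValidationError(f"assignment maps clusters to unknown types: {missing}")
    rng = spec.rng(stream=3)
    weights = dictionary.weights
    rows = []
    for cluster in assignment:
        cell_type = assignment[cluster]
        for gene in dictionary.genes_of(cell_type):
            if spec.dropout and rng.random() < spec.dropout:
                continue
            base = weights[(cell_type, gene)] * 10.0
            noise = math.exp(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd else 1.0
            value = base * noise
            rows.append({
                "p_val": rng.uniform(0.0, 1e-6),
                "avg_log2FC": value,
                "pct.1": rng.uniform(0.5, 1.0),
                "pct.2": rng.uniform(0.0, 0.3),
                "p_val_adj": rng.uniform(0.0, 0.05 * 0.5),
                "cluster": cluster,
                "gene": gene,
            })
    df = pd.DataFrame(
        rows,
        columns=["p_val", "avg_log2FC", "pct.1", "pct.2",
                 "p_val_adj", "cluster", "gene"],
    )
    out = df.rename(columns={"avg_log2FC": "value"})
    return MarkerTable(
        out[["gene", "cluster", "value", "p_val", "pct.1", "pct.2", "p_val_adj"]]
    )


def write_findallmarkers_csv(table: MarkerTable, path) -> None:
    """Write a MarkerTable back out in the FindAllMarkers column order."""
    df = table.data.rename(columns={"value": "avg_log2FC"})
    cols = ["p_val", "avg_log2FC", "pct.1", "pct.2", "p_val_adj", "cluster", "gene"]
    present = [c for c in cols if c in df.columns]
    df[present].to_csv(path, index=False)


def make_annotator_panel(
    spec: SyntheticSpec,
    assignment: dict[str, str],
    error_rates: dict[str, float],
) -> list[LabelTable]:
    """Annotators that reproduce the planted labels with controlled errors.

    Each annotator labels every cluster with the true type with probability
    1 − error_rate, otherwise with a uniformly random *wrong* type, so its
    expected accuracy against the planted truth is exactly 1 − error_rate.
    """
    for name, e in error_rates.items():
        if not 0 <= e <= 1:
            raise ValidationError(f"error rate for '{name}' must lie in [0, 1]")
    rng = spec.rng(stream=4)
    types = [_type_name(t) for t in range(spec.n_cell_types)]
    tables = []
    for name, err in error_rates.items():
        rows = []
        for cluster, truth in assignment.items():
            if err and rng.random() < err:
                wrong = [t for t in types if t != truth]
                label = wrong[int(rng.integers(0, len(wrong)))]
            else:
                label = truth
            rows.append({"cluster": cluster, "label": label})
        tables.append(LabelTable(annotator=name, data=pd.DataFrame(rows)))
    return tables


def write_dataset(spec: SyntheticSpec, outdir, *,
                  n_annotators: int = 6, error_rate: float = 0.1) -> dict:
    """Write a complete synthetic study to ``outdir``.

    Emits ``dictionary.tsv``, ``markers.csv``, ``truth.tsv`` and one
    ``annotator_k.tsv`` per panel member; returns the file map.
    """
    import os

    from .dictionary import write_dictionary

    os.makedirs(outdir, exist_ok=True)
    dictionary, _truth = make_dictionary(spec)
    assignment = default_assignment(spec)
    markers = make_marker_table(spec, dictionary, assignment)
    panel = make_annotator_panel(
        spec, assignment,
        {f"annotator_{k}": error_rate for k in range(n_annotators)},
    )
    paths = {
        "dictionary": os.path.join(outdir, "dictionary.tsv"),
        "markers": os.path.join(outdir, "markers.csv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_dictionary(dictionary, paths["dictionary"])
    write_findallmarkers_csv(markers, paths["markers"])
    pd.DataFrame(
        [{"cluster": c, "label": t} for c, t in assignment.items()]
    ).to_csv(paths["truth"], sep="\t", index=False)
    for t in panel:
        p = os.path.join(outdir, f"{t.annotator}.tsv")
        t.data[["cluster", "label"]].to_csv(p, sep="\t", index=False)
        paths[t.annotator] = p
    return paths
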