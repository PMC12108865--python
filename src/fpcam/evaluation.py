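"""Multi-annotator evaluation against a majority-vote pseudo-reference.

When no expert ground truth exists, a consensus label per cluster is built
by majority voting over the primary labels of several annotation tools
(Boyer–Moore candidate/counter pass, then a verification count; plurality
with a lexicographic tie-break when no strict majority exists).  Each
annotator is then scored by accuracy — matched clusters over all reference
clusters — and pairs of runs of the same tool under different reference
files are compared with the range statistic R = |Acc₁ − Acc₂|, a measure of
how strongly the tool depends on its reference data.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotation import UNANNOTATED
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)


def _norm_label(label) -> str:
    """Trimmed, case-folded comparison form of a label."""
    return str(label).strip().casefold()


@dataclass
class LabelTable:
    """One annotator's per-cluster labels (primary, optional secondary)."""

    annotator: str
    data: pd.DataFrame  # columns: cluster, label[, label2]

    def __post_init__(self) -> None:
        missing = {"cluster", "label"} - set(self.data.columns)
        if missing:
            raise SchemaError(
                f"label table '{self.annotator}' missing columns: {sorted(missing)}"
            )
        df = self.data.copy()
        df["cluster"] = df["cluster"].astype(str).str.strip()
        if df["cluster"].duplicated().any():
            raise ValidationError(
                f"annotator '{self.annotator}' labels a cluster more than once"
            )
        if "label2" not in df.columns:
            df["label2"] = None
        self.data = df.reset_index(drop=True)

    @property
    def clusters(self) -> list[str]:
        return list(self.data["cluster"])

    def labels_of(self, cluster: str) -> tuple[str, str | None]:
        row = self.data[self.data["cluster"] == str(cluster)]
        if not len(row):
            raise KeyError(cluster)
        r = row.iloc[0]
        label2 = r["label2"]
        return str(r["label"]), (None if pd.isna(label2) else str(label2))


def read_label_table(path, name: str | None = None) -> LabelTable:
    """Read a per-annotator TSV (columns cluster, label[, label2])."""
    import os

    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    ren = {cols[k]: k for k in ("cluster", "label", "label2") if k in cols}
    df = df.rename(columns=ren)
    annotator = name or os.path.splitext(os.path.basename(str(path)))[0]
    return LabelTable(annotator=annotator, data=df)


def boyer_moore_majority(votes: Sequence[str]) -> str | None:
    """Boyer–Moore majority vote with verification.

    Single candidate/counter pass over ``votes`` followed by a counting
    pass; returns the candidate only when it is a strict majority
    (> half of the votes), else ``None``.
    """
    candidate, count = None, 0
    for v in votes:
        if count == 0:
            candidate, count = v, 1
        elif v == candidate:
            count += 1
        else:
            count -= 1
    if candidate is None:
        return None
    if sum(1 for v in votes if v == candidate) * 2 > len(votes):
        return candidate
    return None


def majority_reference(tables: Sequence[LabelTable]) -> dict[str, str]:
    """Consensus primary label per cluster over the annotator panel.

    Annotators vote in the order given (a documented, fixed order).  A
    verified Boyer–Moore strict majority wins; otherwise the plurality
    label is used with a lexicographic tie-break and a NO_STRICT_MAJORITY
    log entry.  Clusters missing from an annotator simply contribute no
    vote there.
    """
    if not len(tables):
        raise ValidationError("majority_reference needs at least one label table")
    clusters: list[str] = []
    for t in tables:
        for c in t.clusters:
            if c not in clusters:
                clusters.append(c)
    reference: dict[str, str] = {}
    for cluster in clusters:
        votes = []
        for t in tables:
            try:
                votes.append(t.labels_of(cluster)[0])
            except KeyError:
                continue
        winner = boyer_moore_majority(votes)
        if winner is None:
            counts = Counter(votes)
            top = max(counts.values())
            winner = min(label for label, n in counts.items() if n == top)
            logger.info(
                "NO_STRICT_MAJORITY for cluster %s; plurality fallback → %s",
                cluster, winner,
            )
        reference[cluster] = winner
    return reference


def accuracy(
    predicted: LabelTable,
    reference: Mapping[str, str],
    match_mode: str = "either",
) -> tuple[int, int, float]:
    """Score one annotator against the reference.

    A cluster scores one point when its predicted label equals the
    reference label after trimming and case-folding; ``match_mode="either"``
    also accepts the secondary label.  The denominator is the number of
    reference clusters, so clusters the annotator skipped (or left
    ``Unannotated``) count as errors.

    Returns
    -------
    (matches, total, accuracy)
    """
    if match_mode not in ("either", "primary"):
        raise ValueError(f"unknown match_mode {match_mode!r}")
    if not len(reference):
        raise ValidationError("reference is empty")
    matches = 0
    for cluster, ref_label in reference.items():
        try:
            primary, secondary = predicted.labels_of(cluster)
        except KeyError:
            continue
        candidates = [primary]
        if match_mode == "either" and secondary is not None:
            candidates.append(secondary)
        if any(_norm_label(c) == _norm_label(ref_label) for c in candidates):
            matches += 1
    total = len(reference)
    return matches, total, matches / total


def range_stat(acc1: float, acc2: float) -> float:
    """Range R = |Acc₁ − Acc₂| between two runs of the same model family."""
    return abs(acc1 - acc2)


@dataclass
class EvaluationReport:
    """Per-annotator accuracies and per-family range statistics."""

    reference: dict[str, str]
    per_annotator: pd.DataFrame
    ranges: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.per_annotator.to_csv(path, sep="\t", index=False)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.per_annotator.to_dict(orient="records"):
                import json

                fh.write(json.dumps(rec) + "\n")
            if self.ranges:
                import json

                fh.write(json.dumps({"ranges": self.ranges}) + "\n")


def evaluate_models(
    tables: Sequence[LabelTable],
    pairing: Mapping[str, tuple[str, str]] | None = None,
    *,
    reference: Mapping[str, str] | None = None,
    match_mode: str = "either",
) -> EvaluationReport:
    """Build the pseudo-reference and score every annotator.

    ``pairing`` maps a model family name to the two annotator names whose
    accuracies define its range R.  An explicit ``reference`` replaces the
    majority vote (useful against planted ground truth).
    """
    if not len(tables):
        raise ValidationError("evaluate_models needs at least one label table")
    names = [t.annotator for t in tables]
    if len(set(names)) != len(names):
        raise ValidationError("annotator names collide")
    ref = dict(reference) if reference is not None else majority_reference(tables)
    rows = []
    accs: dict[str, float] = {}
    for t in tables:
        matches, total, acc = accuracy(t, ref, match_mode=match_mode)
        accs[t.annotator] = acc
        labels = pd.concat([t.data["label"], t.data["label2"].dropna()])
        rows.append({
            "annotator": t.annotator,
            "unannotated": bool(
                (labels.map(_norm_label) == _norm_label(UNANNOTATED)).any()
            ),
            "subtype_capable": bool(t.data["label2"].notna().any()),
            "matches": matches,
            "total": total,
            "accuracy": acc,
        })
    ranges: dict[str, float] = {}
    if pairing:
        for family, (a, b) in pairing.items():
            if a not in accs or b not in accs:
                raise ValidationError(
                    f"pairing for '{family}' names unknown annotator(s): {a}, {b}"
                )
            ranges[family] = range_stat(accs[a], accs[b])
    return EvaluationReport(
        reference=ref,
        per_annotator=pd.DataFrame(rows),
        ranges=ranges,
    )
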