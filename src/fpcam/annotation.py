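"""Cluster × cell-type similarity scoring and λ-threshold label assignment.

For a cluster *j* and candidate cell type *m*, the similarity score is

    S[j, m] = Σ_g E[g, j] · W[g, m]

summed over genes *g* shared between the cluster's marker rows and the
type's dictionary entries, where ``E`` is the per-gene expression
proportion and ``W`` the dictionary vote weight.  Labels are then decided
per cluster from its score row:

* λ₁ = S_max − S_median  — the primary criterion.  A cluster is labelled
  with the argmax type when λ₁ > 0; a zero or negative λ has no meaning
  and the cluster stays ``Unannotated``.
* λ₂ = S_secmax − S_median — when the gap S_max − S_secmax exceeds a small
  ε (default 1e-5) and λ₂ > 0, the runner-up type is attached as a
  secondary annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dictionary import MarkerDictionary
from .errors import PipelineError, ValidationError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Sentinel label for clusters whose λ₁ criterion fails.
UNANNOTATED = "Unannotated"

#: Default ε for the λ₂ trigger.
DEFAULT_EPSILON = 1e-5

ANNOTATION_COLUMNS = [
    "cluster", "primary_type", "secondary_type",
    "lambda1", "lambda2", "s_max", "s_secmax", "s_median",
]


@dataclass
class SimilarityMatrix:
    """Cluster × cell-type nonnegative score matrix.

    ``S`` has clusters as the index and every dictionary cell type as a
    column (zero where the cluster shares no marker gene with the type).
    """

    S: pd.DataFrame

    @property
    def clusters(self) -> list[str]:
        return list(self.S.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.S.columns)


@dataclass(frozen=True)
class Thresholds:
    """λ statistics of one cluster's similarity row."""

    s_max: float
    s_secmax: float | None
    s_median: float
    lambda1: float
    lambda2: float | None


def compute_similarity(
    matrix: ExpressionMatrix, dictionary: MarkerDictionary
) -> SimilarityMatrix:
    """Score every cluster against every dictionary cell type.

    Requires ``matrix.E`` (run :func:`fpcam.expression.normalize_expression`
    first).  Gene symbols must be normalized consistently with the
    dictionary; genes absent from either side contribute nothing.
    """
    if matrix.E is None:
        raise ValidationError("expression matrix is not normalized (E missing)")
    W = dictionary.weight_matrix()
    if W.empty:
        raise ValidationError("dictionary has no records")
    shared = matrix.E.index.intersection(W.index)
    if len(shared) == 0:
        logger.warning(
            "no gene symbols shared between expression matrix and dictionary; "
            "all similarity scores are zero"
        )
        S = pd.DataFrame(
            0.0, index=matrix.clusters, columns=dictionary.cell_types
        )
        return SimilarityMatrix(S=S)
    S = matrix.E.loc[shared].T @ W.loc[shared]
    S = S.reindex(columns=dictionary.cell_types, fill_value=0.0)
    S.index.name = "cluster"
    return SimilarityMatrix(S=S.astype(float))


def derive_thresholds(scores, epsilon: float = DEFAULT_EPSILON) -> Thresholds:
    """Compute λ₁/λ₂ statistics for one cluster's score row.

    ``s_secmax`` is taken with multiset semantics: remove one occurrence of
    the maximum, then take the largest remaining value (a tied maximum thus
    yields ``s_secmax == s_max``).  The median runs over the full row, the
    maximum included.  λ₂ is reported only when the top-two gap
    ``s_max − s_secmax`` exceeds ``epsilon``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    row = np.asarray(scores, dtype=float)
    if row.size == 0:
        raise ValidationError("cannot derive thresholds from an empty score row")
    s_max = float(row.max())
    s_median = float(np.median(row))
    lambda1 = s_max - s_median
    if row.size == 1:
        return Thresholds(s_max, None, s_median, lambda1, None)
    rest = np.delete(row, int(row.argmax()))
    s_secmax = float(rest.max())
    lambda2 = s_secmax - s_median if (s_max - s_secmax) > epsilon else None
    return Thresholds(s_max, s_secmax, s_median, lambda1, lambda2)


def assign_labels(
    similarity: SimilarityMatrix,
    epsilon: float = DEFAULT_EPSILON,
    *,
    lambda2_trigger: str = "secmax",
) -> pd.DataFrame:
    """Assign one or two cell-type labels per cluster from its score row.

    The primary label is the argmax type (ties broken lexicographically and
    logged); it is replaced by the ``Unannotated`` sentinel when λ₁ ≤ 0,
    i.e. exactly when the row's maximum equals its median.  The secondary
    label is the type attaining ``s_secmax`` when λ₂ was triggered and is
    strictly positive.

    Parameters
    ----------
    lambda2_trigger:
        ``"secmax"`` (default) triggers λ₂ when ``s_max − s_secmax > ε``;
        ``"median"`` is the alternative reading that triggers on
        ``s_max − s_median > ε``.

    Returns
    -------
    pandas.DataFrame
        One row per cluster, in cluster order, with columns
        ``cluster, primary_type, secondary_type, lambda1, lambda2,
        s_max, s_secmax, s_median``.
    """
    if lambda2_trigger not in ("secmax", "median"):
        raise ValueError(f"unknown lambda2_trigger {lambda2_trigger!r}")
    S = similarity.S
    if S.empty:
        raise ValidationError("similarity matrix is empty")
    records = []
    for cluster, row in S.iterrows():
        th = derive_thresholds(row.to_numpy(), epsilon=epsilon)
        # stable order: score desc, then type name — tie-break is lexicographic
        order = sorted(zip(-row.to_numpy(), row.index))
        best_type = order[0][1]
        tied = [t for s, t in order if -s == th.s_max]
        if len(tied) > 1:
            logger.info(
                "cluster %s: argmax tie among %s; keeping %s",
                cluster, tied, best_type,
            )
        triggered = th.lambda2
        if lambda2_trigger == "median" and th.s_secmax is not None:
            triggered = (
                th.s_secmax - th.s_median if th.lambda1 > epsilon else None
            )
        primary = best_type if th.lambda1 > 0 else UNANNOTATED
        secondary = None
        if primary != UNANNOTATED and triggered is not None and triggered > 0:
            runner = order[1][1]
            if runner != primary:
                secondary = runner
        records.append({
            "cluster": cluster,
            "primary_type": primary,
            "secondary_type": secondary,
            "lambda1": th.lambda1,
            "lambda2": triggered if secondary is not None else None,
            "s_max": th.s_max,
            "s_secmax": th.s_secmax,
            "s_median": th.s_median,
        })
    return pd.DataFrame.from_records(records, columns=ANNOTATION_COLUMNS)


def annotate(
    marker_table_path,
    dictionary_path,
    config=None,
    **overrides,
) -> tuple[pd.DataFrame, SimilarityMatrix]:
    """Run the full annotation pipeline from file paths.

    Thin wrapper over :class:`fpcam.estimator.FPCAMAnnotator`: reads the
    marker table and dictionary, builds and normalizes the expression
    matrix, scores similarities and assigns labels.  ``config`` is a
    :class:`fpcam.config.RunConfig` (or None for defaults); keyword
    overrides take precedence.  Deterministic for fixed inputs.
    """
    from .config import RunConfig
    from .estimator import FPCAMAnnotator

    cfg = (config or RunConfig()).replace(**overrides)
    est = FPCAMAnnotator(
        epsilon=cfg.epsilon,
        value_column=cfg.value_column,
        p_adj_threshold=cfg.p_adj_threshold,
        normalize_axis=cfg.normalize_axis,
        lambda2_trigger=cfg.lambda2_trigger,
        case_fold=cfg.case_fold,
    )
    try:
        est.fit(dictionary_path)
    except Exception as exc:  # noqa: BLE001 - stage naming contract
        raise PipelineError(f"[read_dictionary] {exc}") from exc
    return est.annotate(marker_table_path, return_similarity=True)
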