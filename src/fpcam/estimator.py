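"""Scikit-learn style estimator wrapping the annotation pipeline.

``FPCAMAnnotator`` is fit on a marker dictionary (the reference knowledge)
and then predicts cell-type labels for cluster-level marker tables.  It
follows the scikit-learn estimator contract — ``get_params``/``set_params``,
fitted attributes with a trailing underscore, ``fit``/``transform``/
``predict`` — so it composes with sklearn tooling (``clone``, pipelines).

``transform`` returns the cluster × cell-type similarity matrix;
``predict`` returns the primary label per cluster; ``annotate`` returns the
full per-cluster table with both labels and the λ statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .annotation import SimilarityMatrix, assign_labels, compute_similarity
from .dictionary import MarkerDictionary, read_dictionary
from .errors import PipelineError
from .expression import (
    ExpressionMatrix,
    MarkerTable,
    build_expression_matrix,
    normalize_expression,
    read_marker_table,
)


class FPCAMAnnotator(BaseEstimator):
    """Weighted dictionary-driven cluster annotator.

    Parameters
    ----------
    epsilon:
        Trigger width for the secondary-label rule λ₂ (default 1e-5).
    value_column:
        Marker-table column feeding the expression matrix
        (default ``avg_log2FC``).
    p_adj_threshold:
        Adjusted-p-value screen applied when reading marker tables
        (default 0.05).
    normalize_axis:
        ``"gene"`` (default): proportions per gene across clusters;
        ``"cluster"``: per cluster across genes.
    lambda2_trigger:
        ``"secmax"`` (default) or ``"median"``; see
        :func:`fpcam.annotation.assign_labels`.
    case_fold:
        Upper-case gene symbols when reading inputs (default True).

    Attributes
    ----------
    dictionary_ : MarkerDictionary
        The fitted voting dictionary with computed weights.
    cell_types_ : list of str
        Cell types the annotator can assign.
    n_features_in_ : int
        Number of distinct marker genes in the dictionary.

    Examples
    --------
    >>> est = FPCAMAnnotator().fit("dictionary.tsv")   # doctest: +SKIP
    >>> est.predict("markers.csv")                     # doctest: +SKIP
    array(['B_cell', 'AT2', ...], dtype=object)
    """

    def __init__(
        self,
        epsilon: float = 1e-5,
        value_column: str = "avg_log2FC",
        p_adj_threshold: float = 0.05,
        normalize_axis: str = "gene",
        lambda2_trigger: str = "secmax",
        case_fold: bool = True,
    ):
        self.epsilon = epsilon
        self.value_column = value_column
        self.p_adj_threshold = p_adj_threshold
        self.normalize_axis = normalize_axis
        self.lambda2_trigger = lambda2_trigger
        self.case_fold = case_fold

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None) -> "FPCAMAnnotator":
        """Fit on a marker dictionary.

        ``X`` may be a :class:`~fpcam.dictionary.MarkerDictionary`, a
        dictionary TSV path, or a DataFrame with ``cell_type``, ``gene``,
        ``votes`` and ``total_votes`` columns.  ``y`` is ignored.
        """
        if isinstance(X, MarkerDictionary):
            dictionary = X
        elif isinstance(X, pd.DataFrame):
            dictionary = MarkerDictionary(X)
        else:
            dictionary = read_dictionary(X, case_fold=self.case_fold)
        self.dictionary_ = dictionary
        self.cell_types_ = dictionary.cell_types
        self.n_features_in_ = len(dictionary.genes)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "dictionary_"):
            raise NotFittedError(
                "This FPCAMAnnotator instance is not fitted yet; call 'fit' "
                "with a marker dictionary first."
            )

    # -- input coercion ---------------------------------------------------
    def _as_expression(self, X) -> ExpressionMatrix:
        """Coerce marker-table path / MarkerTable / ExpressionMatrix to a
        normalized ExpressionMatrix, naming the failing stage on error."""
        stage = "read_marker_table"
        try:
            if isinstance(X, ExpressionMatrix):
                matrix = X
            else:
                if isinstance(X, MarkerTable):
                    table = X
                elif isinstance(X, pd.DataFrame):
                    table = MarkerTable(X)
                else:
                    table = read_marker_table(
                        X,
                        value_column=self.value_column,
                        p_adj_threshold=self.p_adj_threshold,
                        case_fold=self.case_fold,
                    )
                stage = "build_expression_matrix"
                matrix = build_expression_matrix(table)
            if matrix.E is None:
                stage = "normalize_expression"
                matrix = normalize_expression(matrix, axis=self.normalize_axis)
            return matrix
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage naming contract
            raise PipelineError(f"[{stage}] {exc}") from exc

    # -- scoring and labelling ---------------------------------------------
    def transform(self, X) -> pd.DataFrame:
        """Similarity scores: clusters as rows, dictionary types as columns."""
        self._check_fitted()
        matrix = self._as_expression(X)
        try:
            return compute_similarity(matrix, self.dictionary_).S
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"[compute_similarity] {exc}") from exc

    def fit_transform(self, X, y=None, dictionary=None) -> pd.DataFrame:
        """Fit on ``dictionary`` and transform ``X`` (dictionary required)."""
        if dictionary is None:
            raise ValueError("fit_transform needs the dictionary= argument")
        return self.fit(dictionary).transform(X)

    def annotate(self, X, *, return_similarity: bool = False):
        """Full annotation table for the clusters of ``X``.

        Returns the per-cluster DataFrame (and the
        :class:`~fpcam.annotation.SimilarityMatrix` when requested).
        """
        self._check_fitted()
        sim = SimilarityMatrix(S=self.transform(X))
        try:
            table = assign_labels(
                sim, epsilon=self.epsilon, lambda2_trigger=self.lambda2_trigger
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"[assign_labels] {exc}") from exc
        return (table, sim) if return_similarity else table

    def predict(self, X) -> np.ndarray:
        """Primary cell-type label per cluster, in cluster order."""
        return self.annotate(X)["primary_type"].to_numpy(dtype=object)

    def _more_tags(self):  # pragma: no cover - sklearn compatibility shim
        return {"requires_fit": True, "X_types": ["string"]}
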