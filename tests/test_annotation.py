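"""Similarity scoring and the λ-threshold labelling rule."""

import numpy as np
import pandas as pd
import pytest

from fpcam import (
    UNANNOTATED,
    ExpressionMatrix,
    MarkerDictionary,
    SimilarityMatrix,
    ValidationError,
    annotate,
    assign_labels,
    compute_similarity,
    derive_thresholds,
    normalize_expression,
    write_dictionary,
)
from fpcam.synthetic import (
    SyntheticSpec,
    default_assignment,
    make_dictionary,
    make_marker_table,
    write_findallmarkers_csv,
)


def brute_force_similarity(E: pd.DataFrame, dictionary: MarkerDictionary):
    """Independent oracle: explicit loop over every (cluster, type, gene)."""
    weights = dictionary.weights
    S = pd.DataFrame(0.0, index=E.columns, columns=dictionary.cell_types)
    for cluster in E.columns:
        for cell_type in dictionary.cell_types:
            total = 0.0
            for gene in E.index:
                if (cell_type, gene) in weights:
                    total += E.loc[gene, cluster] * weights[(cell_type, gene)]
            S.loc[cluster, cell_type] = total
    return S


class TestComputeSimilarity:
    def test_disjoint_gene_sets_score_zero(self, two_type_dictionary):
        A = pd.DataFrame([[1.0]], index=["UNRELATED"], columns=["c0"])
        sim = compute_similarity(
            normalize_expression(ExpressionMatrix(A=A)), two_type_dictionary)
        assert (sim.S.to_numpy() == 0).all()
        assert sim.cell_types == ["T_cell", "B_cell"]

    def test_single_shared_gene_is_one_product(self):
        d = MarkerDictionary(pd.DataFrame(
            [("t", "G1", 1, 5), ("t", "G2", 4, 5)],
            columns=["cell_type", "gene", "votes", "total_votes"]))
        E = pd.DataFrame([[0.5, 0.5]], index=["G1"], columns=["a", "b"])
        sim = compute_similarity(ExpressionMatrix(A=E, E=E), d)
        assert sim.S.loc["a", "t"] == pytest.approx(0.5 * 0.2, abs=1e-15)

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            genes = [f"G{k}" for k in range(rng.integers(3, 30))]
            clusters = [f"c{k}" for k in range(rng.integers(2, 8))]
            types = [f"t{k}" for k in range(rng.integers(2, 6))]
            A = pd.DataFrame(rng.random((len(genes), len(clusters))),
                             index=genes, columns=clusters)
            rows = []
            for t in types:
                chosen = rng.choice(genes, size=rng.integers(1, len(genes)),
                                    replace=False)
                votes = [int(v) for v in rng.integers(1, 6, size=len(chosen))]
                for g, v in zip(chosen, votes):
                    rows.append((t, g, v, sum(votes)))
            d = MarkerDictionary(pd.DataFrame(
                rows, columns=["cell_type", "gene", "votes", "total_votes"]))
            m = normalize_expression(ExpressionMatrix(A=A))
            got = compute_similarity(m, d).S
            want = brute_force_similarity(m.E, d)
            assert np.allclose(got.to_numpy(), want.loc[got.index, got.columns]
                               .to_numpy(), atol=1e-12)

    def test_unnormalized_matrix_rejected(self, two_type_dictionary):
        A = pd.DataFrame([[1.0]], index=["CD3D"], columns=["c0"])
        with pytest.raises(ValidationError, match="not normalized"):
            compute_similarity(ExpressionMatrix(A=A), two_type_dictionary)

    def test_scaling_one_type_weights_scales_only_its_column(
            self, two_type_dictionary, small_marker_table):
        from fpcam import build_expression_matrix

        class ScaledDict(MarkerDictionary):
            """Dictionary whose B_cell weights are scaled by α (bilinearity probe)."""

            alpha = 3.0

            def weight_matrix(self):
                W = super().weight_matrix().copy()
                W["B_cell"] *= self.alpha
                return W

        m = normalize_expression(build_expression_matrix(small_marker_table))
        S = compute_similarity(m, two_type_dictionary).S
        scaled = ScaledDict(two_type_dictionary.data[
            ["cell_type", "gene", "votes", "total_votes"]])
        S2 = compute_similarity(m, scaled).S
        assert np.allclose(S2["B_cell"], 3.0 * S["B_cell"], atol=1e-12)
        assert np.allclose(S2["T_cell"], S["T_cell"], atol=1e-12)


class TestDeriveThresholds:
    def test_worked_row(self):
        th = derive_thresholds([0.5, 0.4, 0.2, 0.1], epsilon=1e-5)
        assert th.s_median == pytest.approx(0.3)
        assert th.lambda1 == pytest.approx(0.2)
        assert th.s_max - th.s_secmax == pytest.approx(0.1)
        assert th.lambda2 == pytest.approx(0.1)

    def test_all_equal_row_has_zero_lambda1(self):
        th = derive_thresholds([0.3, 0.3, 0.3])
        assert th.lambda1 == 0.0

    def test_tied_max_suppresses_lambda2(self):
        # median over the full row [0.1, 0.1, 0.5, 0.5] is 0.3
        th = derive_thresholds([0.5, 0.5, 0.1, 0.1], epsilon=1e-5)
        assert th.lambda1 == pytest.approx(0.2)
        assert th.s_secmax == 0.5  # multiset semantics: tied max remains
        assert th.lambda2 is None  # zero top-two gap fails the trigger

    def test_tied_max_median_row_means_unannotated_lambda(self):
        # with three entries the tied max IS the median, so λ₁ = 0
        th = derive_thresholds([0.5, 0.5, 0.1], epsilon=1e-5)
        assert th.lambda1 == 0.0
        assert th.lambda2 is None

    def test_single_entry_row(self):
        th = derive_thresholds([0.7])
        assert th.lambda1 == 0.0
        assert th.s_secmax is None and th.lambda2 is None

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            derive_thresholds([0.1, 0.2], epsilon=0.0)


class TestAssignLabels:
    @staticmethod
    def sim(rows, clusters, types):
        return SimilarityMatrix(S=pd.DataFrame(rows, index=clusters, columns=types))

    def test_primary_and_secondary_from_worked_row(self):
        table = assign_labels(self.sim([[0.5, 0.4, 0.2, 0.1]], ["c"],
                                       ["t1", "t2", "t3", "t4"]))
        row = table.iloc[0]
        assert row["primary_type"] == "t1"
        assert row["secondary_type"] == "t2"
        assert row["lambda1"] == pytest.approx(0.2)
        assert row["lambda2"] == pytest.approx(0.1)

    def test_all_zero_row_is_unannotated(self):
        table = assign_labels(self.sim([[0.0, 0.0, 0.0]], ["c"], list("abc")))
        assert table.iloc[0]["primary_type"] == UNANNOTATED
        assert table.iloc[0]["secondary_type"] is None

    def test_tied_maxima_lexicographic_primary_no_secondary(self):
        table = assign_labels(self.sim([[0.5, 0.5, 0.1, 0.1]], ["c"],
                                       ["zeta", "alpha", "beta", "gamma"]))
        row = table.iloc[0]
        assert row["primary_type"] == "alpha"
        assert row["secondary_type"] is None  # gap 0 fails the λ₂ trigger

    def test_unannotated_iff_max_equals_median(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            row = rng.random(5).round(2)
            table = assign_labels(self.sim([row], ["c"], list("abcde")))
            is_un = table.iloc[0]["primary_type"] == UNANNOTATED
            assert is_un == (row.max() == np.median(row))

    def test_median_trigger_variant_uses_lambda1_gap(self):
        # top two nearly tied (gap < ε) but both far above the median:
        # the secmax trigger fails while the median trigger fires
        row = [[0.5, 0.5 - 1e-7, 0.1, 0.1]]
        table_sec = assign_labels(self.sim(row, ["c"], list("abcd")),
                                  lambda2_trigger="secmax")
        table_med = assign_labels(self.sim(row, ["c"], list("abcd")),
                                  lambda2_trigger="median")
        assert table_sec.iloc[0]["secondary_type"] is None
        assert table_med.iloc[0]["secondary_type"] == "b"

    def test_empty_similarity_rejected(self):
        with pytest.raises(ValidationError):
            assign_labels(SimilarityMatrix(S=pd.DataFrame()))


class TestAnnotatePipeline:
    def test_zero_noise_recovery_of_planted_types(self, tmp_path):
        spec = SyntheticSpec(n_cell_types=6, n_clusters=6, seed=11)
        dictionary, _ = make_dictionary(spec)
        assignment = default_assignment(spec)
        markers = make_marker_table(spec, dictionary, assignment)
        mpath, dpath = tmp_path / "m.csv", tmp_path / "d.tsv"
        write_findallmarkers_csv(markers, mpath)
        write_dictionary(dictionary, dpath)
        table, sim = annotate(mpath, dpath)
        got = dict(zip(table["cluster"].astype(str), table["primary_type"]))
        assert got == assignment
        assert (sim.S.to_numpy() >= 0).all()

    def test_dictionary_row_permutation_changes_nothing(self, tmp_path):
        spec = SyntheticSpec(n_cell_types=5, n_clusters=5, seed=3)
        dictionary, _ = make_dictionary(spec)
        markers = make_marker_table(spec, dictionary, default_assignment(spec))
        mpath = tmp_path / "m.csv"
        write_findallmarkers_csv(markers, mpath)
        d1, d2 = tmp_path / "d1.tsv", tmp_path / "d2.tsv"
        write_dictionary(dictionary, d1)
        permuted = MarkerDictionary(
            dictionary.data.sample(frac=1.0, random_state=0)
            [["cell_type", "gene", "votes", "total_votes"]])
        write_dictionary(permuted, d2)
        t1, s1 = annotate(mpath, d1)
        t2, s2 = annotate(mpath, d2)
        assert t1["primary_type"].tolist() == t2["primary_type"].tolist()
        pd.testing.assert_frame_equal(
            s1.S.sort_index(axis=1), s2.S.sort_index(axis=1))

    def test_no_gene_overlap_yields_all_unannotated(self, tmp_path, caplog):
        spec = SyntheticSpec(n_cell_types=4, n_clusters=4, seed=5)
        dictionary, _ = make_dictionary(spec)
        markers = make_marker_table(spec, dictionary, default_assignment(spec))
        df = markers.data.copy()
        df["gene"] = "XX" + df["gene"]  # break the overlap
        from fpcam import MarkerTable
        mpath, dpath = tmp_path / "m.csv", tmp_path / "d.tsv"
        write_findallmarkers_csv(MarkerTable(df), mpath)
        write_dictionary(dictionary, dpath)
        with caplog.at_level("WARNING"):
            table, _ = annotate(mpath, dpath)
        assert (table["primary_type"] == UNANNOTATED).all()
        assert "no gene symbols shared" in caplog.text

    def test_epsilon_isolates_secondary_labels(self, tmp_path):
        spec = SyntheticSpec(n_cell_types=6, n_clusters=6, seed=7,
                             marker_overlap=0.4, noise_sd=0.5)
        dictionary, _ = make_dictionary(spec)
        markers = make_marker_table(spec, dictionary, default_assignment(spec))
        mpath, dpath = tmp_path / "m.csv", tmp_path / "d.tsv"
        write_findallmarkers_csv(markers, mpath)
        write_dictionary(dictionary, dpath)
        t_small, _ = annotate(mpath, dpath, epsilon=1e-5)
        t_big, _ = annotate(mpath, dpath, epsilon=10.0)
        assert t_small["primary_type"].tolist() == t_big["primary_type"].tolist()
        assert t_big["secondary_type"].isna().all()

    def test_stage_names_surface_in_errors(self, tmp_path, basal_tsv):
        bad = tmp_path / "bad.csv"
        bad.write_text("not,a,marker,table\n1,2,3,4\n")
        with pytest.raises(Exception, match=r"\[read_marker_table\]"):
            annotate(bad, basal_tsv)
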