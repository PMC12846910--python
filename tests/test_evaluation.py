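import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ickg import (
    AliasTable,
    ConfusionMatrix,
    EmbeddingSet,
    HashingEmbedder,
    centroid_distance,
    gmm_dichotomize,
    jaccard_index,
    ppi_network_metrics,
    prf_from_confusion,
    relation_confusion,
    simplify_kegg_interaction,
    wcss,
)
from ickg.evaluation import compare_dispersion, degs_to_reference
from ickg.types import Direction, RelationTriple, ValidationError


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B"}, {"B", "C"}, 1 / 3),
            ({"A", "B"}, {"A", "B"}, 1.0),
            ({"A"}, {"B"}, 0.0),
            (set(), set(), 0.0),
            (set(), {"A"}, 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert jaccard_index(a, b) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    def test_symmetric_and_unit_iff_equal(self, a, b):
        assert jaccard_index(a, b) == jaccard_index(b, a)
        if a or b:
            assert (jaccard_index(a, b) == 1.0) == (a == b)


class TestKeggSimplification:
    @pytest.mark.parametrize(
        "subtype,expected",
        [
            ("activation", "activate"),
            ("activation-indirect effect", "activate"),
            ("activation-indirect", "activate"),
            ("inhibition", "inhibit"),
            ("inhibition-indirect effect", "inhibit"),
            ("inhibition-repression", "inhibit"),
            ("repression-indirect effect", "inhibit"),
            ("binding/association", "excluded"),
            ("phosphorylation", "excluded"),
            ("", "excluded"),
        ],
    )
    def test_mapping_table(self, subtype, expected):
        assert simplify_kegg_interaction(subtype) == expected

    def test_case_and_whitespace_insensitive(self):
        assert simplify_kegg_interaction(" Activation ") == "activate"


def t(s, tgt, d, pmid="p1"):
    return RelationTriple(source=s, target=tgt, direction=Direction(d), abstract_id=pmid)


class TestRelationConfusion:
    def test_agreement_fills_a(self):
        m = relation_confusion([t("X", "Y", "activate")], [("X", "Y", "activate")])
        assert (m.a, m.b, m.c, m.d, m.overlap) == (1, 0, 0, 0, 1)

    def test_alias_expansion_with_disagreement(self):
        aliases = AliasTable({"p53": "TP53"})
        m = relation_confusion(
            [t("p53", "MDM2", "activate")], [("TP53", "MDM2", "inhibit")], aliases
        )
        assert (m.a, m.b, m.c, m.d) == (0, 1, 0, 0)

    def test_non_overlapping_pairs_ignored(self):
        m = relation_confusion([t("A", "B", "activate")], [("C", "D", "inhibit")])
        assert m.overlap == 0

    def test_majority_vote_on_conflicting_predictions(self):
        pred = [t("A", "B", "inhibit", "p1"), t("A", "B", "inhibit", "p2"),
                t("A", "B", "activate", "p3")]
        m = relation_confusion(pred, [("A", "B", "inhibit")])
        assert m.d == 1 and m.overlap == 1


class TestPRF:
    def test_balanced_case(self):
        m = prf_from_confusion(ConfusionMatrix(a=30, b=10, c=10, d=0))
        assert (m.precision, m.recall, m.f1) == (0.75, 0.75, 0.75)

    def test_precision_only(self):
        assert prf_from_confusion(ConfusionMatrix(a=9, b=1)).precision == pytest.approx(0.9)

    def test_zero_agreement(self):
        m = prf_from_confusion(ConfusionMatrix(a=0, b=5, c=3, d=2))
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)


def test_degs_to_reference_sign_and_threshold():
    ref = degs_to_reference(
        ["A", "B", "C", "D"], [2.0, -1.5, 0.1, -0.1], "NK cell", lfc_threshold=0.5
    )
    assert ref == [("A", "NK cell", "activate"), ("B", "NK cell", "inhibit")]


class TestGMM:
    def test_separated_clusters(self):
        labels = gmm_dichotomize([0, 0, 0, 1, 1, 1], seed=0)
        assert labels == ["Low", "Low", "Low", "High", "High", "High"]

    def test_order_invariance(self):
        vals = [0.1, 5.2, 0.0, 4.9, 0.2, 5.1]
        a = gmm_dichotomize(vals, seed=0)
        b = gmm_dichotomize(vals[::-1], seed=0)
        assert a == b[::-1]

    def test_parameter_recovery_on_simulation(self):
        rng = np.random.default_rng(12)
        low = rng.normal(0.0, 0.1, 100)
        high = rng.normal(5.0, 0.1, 100)
        values = np.concatenate([low, high])
        labels = gmm_dichotomize(values.tolist(), seed=0)
        truth = ["Low"] * 100 + ["High"] * 100
        agree = np.mean([a == b for a, b in zip(labels, truth)])
        assert agree >= 0.95

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            gmm_dichotomize([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            gmm_dichotomize([0.0, 1.0])


class TestPPIMetrics:
    def test_triangle(self):
        density, clustering, modularity = ppi_network_metrics(
            [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)]
        )
        assert density == pytest.approx(1.0)
        assert clustering == pytest.approx(1.0)

    def test_path_graph(self):
        density, clustering, _ = ppi_network_metrics(
            [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)]
        )
        assert density == pytest.approx(0.5)
        assert clustering == 0.0

    def test_density_matches_hand_formula(self):
        rng = np.random.default_rng(4)
        edges = set()
        while len(edges) < 30:
            a, b = rng.integers(0, 20, size=2)
            if a != b:
                edges.add((min(a, b), max(a, b)))
        density, _, _ = ppi_network_metrics([(f"n{a}", f"n{b}", 1.0) for a, b in edges])
        nodes = {x for e in edges for x in e}
        n = len(nodes)
        assert density == pytest.approx(2 * len(edges) / (n * (n - 1)))

    def test_empty_edge_list(self):
        assert ppi_network_metrics([]) == (0.0, 0.0, 0.0)


class TestEmbeddingMetrics:
    def test_wcss_zero_for_identical_points(self):
        es = EmbeddingSet(labels=["a", "b"], vectors=[[1.0, 2.0], [1.0, 2.0]])
        assert wcss(es) == 0.0

    def test_wcss_two_points_1d(self):
        es = EmbeddingSet(labels=["a", "b"], vectors=[[0.0], [2.0]])
        assert wcss(es) == pytest.approx(2.0)

    def test_centroid_distance_identical_sets(self):
        es = EmbeddingSet(labels=["a", "b"], vectors=[[0.0, 1.0], [2.0, 3.0]])
        assert centroid_distance(es, es) == 0.0

    def test_dimension_mismatch(self):
        a = EmbeddingSet(labels=["a"], vectors=[[0.0, 1.0]])
        b = EmbeddingSet(labels=["b"], vectors=[[0.0, 1.0, 2.0]])
        with pytest.raises(ValidationError):
            centroid_distance(a, b)

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(
            st.lists(st.floats(-10, 10), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        ),
        st.floats(-5, 5),
        st.floats(0.1, 3.0),
    )
    def test_wcss_translation_invariant_scales_quadratically(self, pts, shift, scale):
        base = EmbeddingSet(labels=[str(i) for i in range(len(pts))], vectors=pts)
        shifted = EmbeddingSet(base.labels, base.vectors + shift)
        scaled = EmbeddingSet(base.labels, base.vectors * scale)
        w = wcss(base)
        assert wcss(shifted) == pytest.approx(w, abs=1e-6 * max(1.0, w))
        assert wcss(scaled) == pytest.approx(scale**2 * w, rel=1e-6, abs=1e-8)

    def test_hashing_embedder_deterministic(self):
        emb = HashingEmbedder(dim=32)
        v1 = emb.embed(["nk cell cytotoxicity", "antigen presentation"])
        v2 = emb.embed(["nk cell cytotoxicity", "antigen presentation"])
        assert np.allclose(v1, v2)
        assert not np.allclose(v1[0], v1[1])

    def test_compare_dispersion_reports_standard_tests(self):
        rng = np.random.default_rng(0)
        a = EmbeddingSet([str(i) for i in range(20)], rng.normal(0, 1, (20, 4)))
        b = EmbeddingSet([str(i) for i in range(20)], rng.normal(0, 3, (20, 4)))
        out = compare_dispersion(a, b)
        assert out["wcss_a"] < out["wcss_b"]
        assert 0 <= out["levene_p"] <= 1 and 0 <= out["mannwhitney_p"] <= 1
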