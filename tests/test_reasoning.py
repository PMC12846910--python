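import numpy as np
import pytest
from scipy import stats as ss

from helpers import dense_pagerank, gene_star_with_candidate, random_ickg
from ickg import (
    adjusted_random_walk,
    annotate_gene_set,
    concept_associated_genes,
    concept_similarity_matrix,
    explain_paths,
    in_silico_perturbation,
    jaccard_index,
    permutation_test,
    personalized_pagerank,
    shuffle_graph,
)
from ickg.graph import ICKG
from ickg.reasoning import transition_probabilities
from ickg.types import NodeType, PageRankConfig, RandomWalkConfig, ValidationError


def simple_graph(edges):
    """edges: (src, tgt, direction, weight) with gene/pathway inferred from name."""
    g = ICKG()
    for s, t, direction, w in edges:
        for name in (s, t):
            node_type = NodeType.PATHWAY if name.startswith("P") else NodeType.GENE
            g.add_entity(name, node_type)
        g.add_edge(
            (s, "pathway" if s.startswith("P") else "gene"),
            (t, "pathway" if t.startswith("P") else "gene"),
            key=direction,
            direction=direction,
            weight=w,
            provenance=frozenset(f"{s}-{t}-{direction}-{i}" for i in range(w)),
        )
    return g


class TestPersonalizedPageRank:
    def test_two_node_cycle_symmetry(self):
        g = simple_graph([("A", "B", "activate", 1), ("B", "A", "activate", 1)])
        scores = personalized_pagerank(g)
        assert list(scores.values()) == pytest.approx([0.5, 0.5])

    def test_restart_mass_lower_bound(self):
        g = simple_graph([("A", "B", "activate", 1), ("C", "A", "activate", 1)])
        g.remove_edge(("C", "gene"), ("A", "gene"))
        scores = personalized_pagerank(g, ["A"], PageRankConfig(alpha=0.85))
        assert scores[("A", "gene")] >= 0.15

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_oracle(self, seed):
        g = random_ickg(seed, n_nodes=12, n_edges=30)
        seeds = sorted(g.gene_nodes())[:2]
        mine = personalized_pagerank(g, seeds)
        oracle = dense_pagerank(g, seeds)
        l1 = sum(abs(mine[v] - oracle[v]) for v in mine)
        assert l1 <= 1e-8
        assert sum(mine.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_networkx(self):
        import networkx as nx

        g = random_ickg(3, n_nodes=15, n_edges=40)
        seeds = sorted(g.gene_nodes())[:3]
        mine = personalized_pagerank(g, seeds)
        collapsed = nx.DiGraph()
        collapsed.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            w = collapsed.get_edge_data(u, v, {}).get("weight", 0)
            collapsed.add_edge(u, v, weight=w + d["weight"])
        theirs = nx.pagerank(
            collapsed, alpha=0.85, personalization={s: 1.0 for s in seeds},
            weight="weight", tol=1e-12, max_iter=500,
        )
        assert sum(abs(mine[v] - theirs[v]) for v in mine) <= 1e-6

    def test_unknown_personalization_node_listed(self):
        g = simple_graph([("A", "B", "activate", 1)])
        with pytest.raises(ValidationError, match="NOPE"):
            personalized_pagerank(g, ["A", "NOPE"])


class TestPermutationTest:
    def test_p_is_n_over_n_perm(self):
        g, cand = gene_star_with_candidate(10, seed=1, n_extra_edges=10)
        table = permutation_test(g, [("g0", "gene"), ("g1", "gene")],
                                 candidate_nodes=[cand], n_perm=250, seed=4)
        p = table.p_value[cand]
        assert 0.0 <= p <= 1.0
        assert (p * 250) == pytest.approx(round(p * 250))
        assert table.ci_low[cand] <= table.ci_high[cand]

    def test_unbeatable_observed_gives_p_zero(self):
        # Candidate reachable only from g0; seeding g0 beats every permutation
        # that misses it, so p stays at the floor n/N with n counting ties.
        g = simple_graph(
            [("g0", "P0", "activate", 5)]
            + [(f"g{i}", f"g{i+1}", "activate", 1) for i in range(1, 8)]
        )
        table = permutation_test(g, ["g0"], candidate_nodes=[("P0", "pathway")],
                                 n_perm=100, seed=0)
        draws_with_g0 = table.p_value[("P0", "pathway")]
        assert draws_with_g0 <= 0.2  # only draws containing g0 can tie

    def test_deterministic_under_fixed_seed(self):
        g, cand = gene_star_with_candidate(12, seed=2, n_extra_edges=15)
        t1 = permutation_test(g, [("g0", "gene")], n_perm=50, seed=9)
        t2 = permutation_test(g, [("g0", "gene")], n_perm=50, seed=9)
        assert t1.p_value == t2.p_value and t1.ci_low == t2.ci_low

    def test_seed_set_larger_than_permutation_pool_rejected(self):
        g = simple_graph([("A", "B", "activate", 1)])
        with pytest.raises(ValidationError, match="fewer"):
            permutation_test(
                g, ["A", "B"], n_perm=10, seed=0, permute_type=NodeType.PATHWAY
            )


class TestAdjustedRandomWalk:
    def test_closed_form_two_edges(self):
        g = simple_graph([("A", "B", "activate", 1), ("A", "C", "activate", 2)])
        probs = transition_probabilities(g, "A", temperature=1.0)
        e1, e2 = np.exp(1), np.exp(2)
        assert probs[("B", "gene")] == pytest.approx(e1 / (e1 + e2))
        assert probs[("C", "gene")] == pytest.approx(e2 / (e1 + e2))

    @pytest.mark.parametrize("temperature", [0.1, 1.0, 10.0])
    def test_equal_weights_uniform(self, temperature):
        g = simple_graph([("A", x, "activate", 3) for x in ("B", "C", "D")])
        probs = transition_probabilities(g, "A", temperature)
        assert list(probs.values()) == pytest.approx([1 / 3] * 3)

    def test_high_temperature_limit_is_uniform(self):
        g = simple_graph([("A", "B", "activate", 1), ("A", "C", "activate", 9)])
        probs = transition_probabilities(g, "A", temperature=1e6)
        assert probs[("B", "gene")] == pytest.approx(0.5, abs=1e-5)

    def test_frequencies_sum_to_one_and_reproducible(self):
        g = random_ickg(5, n_nodes=15, n_edges=35)
        cfg = RandomWalkConfig(n_walks=200, walk_length=10, seed=3)
        f1 = adjusted_random_walk(g, [sorted(g.nodes)[0]], cfg)
        f2 = adjusted_random_walk(g, [sorted(g.nodes)[0]], cfg)
        assert f1 == f2
        assert sum(f1.values()) == pytest.approx(1.0)

    def test_sampled_steps_match_softmax(self):
        g = simple_graph(
            [("A", "B", "activate", 1), ("A", "C", "activate", 2), ("A", "D", "activate", 3)]
        )
        cfg = RandomWalkConfig(temperature=1.0, n_walks=10_000, walk_length=1, seed=0)
        freq = adjusted_random_walk(g, ["A"], cfg)
        # Each walk visits the start plus exactly one neighbor.
        counts = np.array(
            [freq[(x, "gene")] * 20_000 for x in ("B", "C", "D")]
        )
        probs = transition_probabilities(g, "A", 1.0)
        expected = np.array([probs[(x, "gene")] for x in ("B", "C", "D")]) * 10_000
        assert ss.chisquare(counts, expected).pvalue > 0.001

    def test_invalid_temperature(self):
        with pytest.raises(ValidationError):
            RandomWalkConfig(temperature=0.0)


class TestPerturbation:
    def test_activation_chain_monotone(self):
        g = simple_graph([("G", "A", "activate", 2), ("A", "B", "activate", 2)])
        res = in_silico_perturbation(g, "G")
        ranked = {name: (score, sign) for name, score, sign in res.ranked_genes}
        assert ranked["A"][1] == "activated" and ranked["B"][1] == "activated"
        assert ranked["A"][0] > ranked["B"][0]

    def test_sign_parity_flips_on_inhibit(self):
        g = simple_graph([("G", "A", "activate", 1), ("A", "B", "inhibit", 1)])
        res = in_silico_perturbation(g, "G")
        signs = {name: sign for name, _s, sign in res.ranked_genes}
        assert signs == {"A": "activated", "B": "inhibited"}

    def test_double_inhibition_activates(self):
        g = simple_graph([("G", "A", "inhibit", 1), ("A", "B", "inhibit", 1)])
        res = in_silico_perturbation(g, "G")
        signs = {name: sign for name, _s, sign in res.ranked_genes}
        assert signs == {"A": "inhibited", "B": "activated"}

    def test_excludes_perturbed_and_scores_non_increasing(self, planted_reasoning):
        g, truth = planted_reasoning
        res = in_silico_perturbation(g, truth.hub)
        names = [n for n, _s, _g in res.ranked_genes]
        assert truth.hub not in names
        scores = [s for _n, s, _g in res.ranked_genes]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_planted_targets_beat_shuffled_control(self, planted_reasoning):
        g, truth = planted_reasoning

        def top10(graph):
            scores = personalized_pagerank(graph, [truth.hub])
            ranked = sorted(
                (v for v in graph.gene_nodes() if v[0] != truth.hub),
                key=lambda v: (-scores[v], v),
            )
            return {v[0] for v in ranked[:10]}

        planted = jaccard_index(top10(g), truth.hub_targets)
        control = jaccard_index(top10(shuffle_graph(g, seed=99)), truth.hub_targets)
        assert planted > control


class TestExplainPaths:
    def test_direct_edge(self):
        g = simple_graph([("A", "B", "activate", 1)])
        res = explain_paths(g, "A", ["B"])
        assert res.paths[("B", "gene")] == [("A", "gene"), ("B", "gene")]

    def test_tiebreak_prefers_heavier_bottleneck(self):
        g = simple_graph(
            [
                ("S", "X", "activate", 5), ("X", "T", "activate", 5),
                ("S", "Y", "activate", 1), ("Y", "T", "activate", 1),
            ]
        )
        res = explain_paths(g, "S", ["T"])
        assert res.paths[("T", "gene")][1] == ("X", "gene")

    def test_unreachable_reported(self):
        g = simple_graph([("A", "B", "activate", 1), ("C", "D", "activate", 1)])
        res = explain_paths(g, "A", ["B", "D"])
        assert res.unreachable == {("D", "gene")}
        assert ("D", "gene") not in res.subgraph.nodes

    def test_subgraph_preserves_edge_metadata(self):
        g = simple_graph([("A", "B", "inhibit", 3)])
        res = explain_paths(g, "A", ["B"])
        d = res.subgraph.get_edge_data(("A", "gene"), ("B", "gene"), "inhibit")
        assert d["weight"] == 3 and d["provenance"]


class TestAnnotation:
    def test_planted_pathway_ranked_first(self, planted_reasoning):
        g, truth = planted_reasoning
        res = annotate_gene_set(g, sorted(truth.pathway_members), n_perm=300, seed=1)
        assert res.rows[0][0] == truth.pathway
        assert res.rows[0][2] < 0.05

    def test_gene_order_irrelevant(self, planted_reasoning):
        g, truth = planted_reasoning
        members = sorted(truth.pathway_members)
        a = annotate_gene_set(g, members, n_perm=50, seed=2)
        b = annotate_gene_set(g, members[::-1], n_perm=50, seed=2)
        assert a.rows == b.rows

    def test_no_reachable_pathway_gives_empty(self):
        g = simple_graph([("A", "B", "activate", 1), ("C", "P1", "activate", 1)])
        res = annotate_gene_set(g, ["A"], n_perm=20, seed=0)
        assert res.rows == []

    def test_unmapped_reported_and_all_unmapped_is_error(self, planted_reasoning):
        g, truth = planted_reasoning
        res = annotate_gene_set(
            g, sorted(truth.pathway_members) + ["NOTAGENE"], n_perm=20, seed=0
        )
        assert res.unmapped == ["NOTAGENE"]
        with pytest.raises(ValidationError, match="NOTAGENE"):
            annotate_gene_set(g, ["NOTAGENE"], n_perm=20, seed=0)


class TestConceptAssociation:
    def concept_graph(self):
        # 50 genes; g1-g3 / g3-g5 are dedicated regulators of the concepts
        # (no other out-edges), the rest carry random background wiring.
        rng = np.random.default_rng(17)
        edges = [(f"g{i}", "P_X", "activate", 4) for i in (1, 2, 3)]
        edges += [(f"g{i}", "P_Y", "activate", 4) for i in (3, 4, 5)]
        seen = set()
        while len(seen) < 60:
            a, b = rng.integers(6, 50, size=2)
            if a != b and (a, b) not in seen:
                seen.add((a, b))
                edges.append((f"g{a}", f"g{b}", "activate", int(rng.integers(1, 4))))
        g = simple_graph(edges)
        for i in range(50):
            g.add_entity(f"g{i}", NodeType.GENE)
        return g

    def test_isolated_concept_empty(self):
        g = self.concept_graph()
        g.add_entity("P_LONE", NodeType.PATHWAY)
        assert concept_associated_genes(g, "P_LONE", n_perm=50, seed=0) == set()

    def test_planted_in_neighbors_recovered(self):
        g = self.concept_graph()
        got = concept_associated_genes(g, "P_X", n_perm=300, seed=5)
        assert got == {"g1", "g2", "g3"}

    def test_threshold_zero_empty(self):
        g = self.concept_graph()
        assert concept_associated_genes(g, "P_X", n_perm=50, seed=0, significance=0.0) == set()

    def test_similarity_matrix_symmetric_unit_diagonal(self):
        g = self.concept_graph()
        mat = concept_similarity_matrix(g, ["P_X", "P_Y"], n_perm=300, seed=5)
        assert mat.loc["P_X", "P_X"] == 1.0
        assert mat.loc["P_X", "P_Y"] == mat.loc["P_Y", "P_X"]
        # associated sets are {g1,g2,g3} and {g3,g4,g5}: overlap 1 of 5
        assert mat.loc["P_X", "P_Y"] == pytest.approx(0.2)


class TestShuffle:
    def test_degree_sequences_and_multisets_preserved(self, planted_reasoning):
        g, _ = planted_reasoning
        sh = shuffle_graph(g, seed=21)
        assert sorted(dict(g.in_degree()).values()) == sorted(dict(sh.in_degree()).values())
        assert dict(g.out_degree()) == dict(sh.out_degree())
        weights = sorted(d["weight"] for *_e, d in g.edges(data=True))
        assert weights == sorted(d["weight"] for *_e, d in sh.edges(data=True))
        signs = sorted(d["direction"] for *_e, d in g.edges(data=True))
        assert signs == sorted(d["direction"] for *_e, d in sh.edges(data=True))

    def test_same_seed_same_shuffle(self, planted_reasoning):
        g, _ = planted_reasoning
        from ickg import graphs_equal

        assert graphs_equal(shuffle_graph(g, seed=4), shuffle_graph(g, seed=4))

    def test_rewiring_changes_connectivity(self, planted_reasoning):
        g, _ = planted_reasoning
        from ickg import graphs_equal

        assert not graphs_equal(shuffle_graph(g, seed=4), g)

    def test_tiny_graph_returned_unchanged(self, caplog):
        g = simple_graph([("A", "B", "activate", 1)])
        from ickg import graphs_equal

        sh = shuffle_graph(g, seed=0)
        assert graphs_equal(sh, g)
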