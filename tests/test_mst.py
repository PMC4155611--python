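"""Vertex-derived edge weights, exact MSTs, and mutation resampling."""

import itertools

import networkx as nx
import numpy as np
import pytest

import protier as p

from conftest import wgraph


def enumerate_spanning_trees(g, weight="weight"):
    """All spanning trees by brute force over edge subsets (independent oracle)."""
    edges = list(g.edges(data=weight))
    n = g.number_of_nodes()
    trees = []
    for subset in itertools.combinations(edges, n - 1):
        t = nx.Graph()
        t.add_nodes_from(g)
        t.add_edges_from((u, v) for u, v, _ in subset)
        if nx.is_connected(t):
            trees.append((sum(w for _, _, w in subset), subset))
    return trees


def random_weighted_instance(rng, n_max=8):
    while True:
        n = int(rng.integers(3, n_max + 1))
        g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(0, 2**31)))
        if nx.is_connected(g):
            break
    for u, v in g.edges:
        # small integer weights make ties (and non-unique MSTs) common
        g.edges[u, v]["weight"] = float(rng.integers(1, 6))
    return g


class TestEdgeWeights:
    def triangle(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        for v, w in zip("abc", (1.0, 2.0, 3.0)):
            g.add_node(v, weight=w)
        return g

    def test_sum_scheme(self):
        g = p.vertex_to_edge_weights(self.triangle(), "weight", "sum")
        assert {frozenset(e): g.edges[e]["weight"] for e in g.edges} == {
            frozenset(("a", "b")): 3.0,
            frozenset(("b", "c")): 5.0,
            frozenset(("a", "c")): 4.0,
        }

    def test_average_scheme_is_half_the_sum(self):
        s = p.vertex_to_edge_weights(self.triangle(), "weight", "sum")
        a = p.vertex_to_edge_weights(self.triangle(), "weight", "average")
        for e in s.edges:
            assert a.edges[e]["weight"] == pytest.approx(s.edges[e]["weight"] / 2)

    def test_missing_descriptor_named(self):
        with pytest.raises(ValueError, match="nope"):
            p.vertex_to_edge_weights(self.triangle(), "nope")

    def test_nested_weight_vectors_supported(self, valine_hierarchy):
        g = p.vertex_to_edge_weights(valine_hierarchy.top, "max_weighted_degree:Hydpthy")
        for _u, _v, d in g.edges(data=True):
            assert isinstance(d["weight"], float)


class TestMinimumSpanningTree:
    def test_tree_input_is_its_own_unique_mst(self):
        t = nx.random_labeled_tree(7, seed=1)
        for u, v in t.edges:
            t.edges[u, v]["weight"] = 1.0
        r = p.minimum_spanning_tree(t)
        assert set(map(frozenset, r.edges)) == set(map(frozenset, t.edges))
        assert r.unique

    def test_triangle_distinct_weights(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 2.0), ("a", "c", 3.0)])
        r = p.minimum_spanning_tree(g)
        assert set(map(frozenset, r.edges)) == {frozenset("ab"), frozenset("bc")}
        assert r.total_weight == 3.0 and r.unique

    def test_symmetric_triangle_not_unique(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        r = p.minimum_spanning_tree(g)
        assert r.total_weight == 2.0 and not r.unique

    def test_disconnected_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        g.add_edge("a", "b", weight=1.0)
        with pytest.raises(ValueError, match="component"):
            p.minimum_spanning_tree(g)

    def test_degrees_sum_to_twice_edge_count(self, square_hierarchy):
        g = p.vertex_to_edge_weights(square_hierarchy.top, "max_weighted_degree:Hydpthy")
        r = p.minimum_spanning_tree(g)
        assert sum(r.degrees.values()) == 2 * (g.number_of_nodes() - 1)

    @pytest.mark.parametrize("seed", range(4))
    def test_exactness_and_uniqueness_vs_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            g = random_weighted_instance(rng)
            r = p.minimum_spanning_tree(g)
            trees = enumerate_spanning_trees(g)
            best = min(w for w, _ in trees)
            assert r.total_weight == pytest.approx(best)
            n_optimal = sum(1 for w, _ in trees if abs(w - best) < 1e-9)
            assert r.unique == (n_optimal == 1)

    @pytest.mark.parametrize("seed", range(4))
    def test_scheme_equivalence_on_random_vertex_weights(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = nx.gnp_random_graph(7, 0.5, seed=seed)
        while not nx.is_connected(g):
            g = nx.gnp_random_graph(7, 0.5, seed=seed + 1000)
        for v in g.nodes:
            g.nodes[v]["weight"] = float(rng.integers(1, 5))
        r_sum = p.minimum_spanning_tree(p.vertex_to_edge_weights(g, "weight", "sum"))
        r_avg = p.minimum_spanning_tree(p.vertex_to_edge_weights(g, "weight", "average"))
        assert set(map(frozenset, r_sum.edges)) == set(map(frozenset, r_avg.edges))
        assert r_sum.unique == r_avg.unique

    def test_maximize_flag(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 2.0), ("a", "c", 3.0)])
        r = p.minimum_spanning_tree(g, maximize=True)
        assert r.total_weight == 5.0


class TestMstForMutations:
    def test_empty_subset_is_wild_type_mst(self, square_hierarchy, table):
        wild = p.minimum_spanning_tree(
            p.vertex_to_edge_weights(square_hierarchy.top, "max_weighted_degree:Hydpthy")
        )
        got = p.mst_for_mutations(square_hierarchy, [], table, "max_weighted_degree:Hydpthy")
        assert got.edges == wild.edges and got.total_weight == wild.total_weight

    def test_weight_neutral_mutation_keeps_wild_mst(self, square_hierarchy, table):
        # Leu and Ile share vanderWaal volume 4.00, so an I→L swap is
        # weight-neutral for that descriptor
        specs = [p.parse_mutation("I4L")]
        wild = p.mst_for_mutations(square_hierarchy, [], table, "max_weighted_degree:vanderWaal")
        got = p.mst_for_mutations(square_hierarchy, specs, table, "max_weighted_degree:vanderWaal")
        assert got.edges == wild.edges

    def test_disjoint_mutation_sets_can_flip_the_tree(self, square_hierarchy, table):
        desc = "max_weighted_degree:Hydpthy"
        # hydrophobic mutations in D3 vs hydrophilic mutations in D2
        a = [p.parse_mutation(m) for m in ("S7I", "S8I", "S9I")]
        b = [p.parse_mutation(m) for m in ("I4R", "I5R", "I6R")]
        ra = p.mst_for_mutations(square_hierarchy, a, table, desc)
        rb = p.mst_for_mutations(square_hierarchy, b, table, desc)
        assert set(map(frozenset, ra.edges)) != set(map(frozenset, rb.edges))

    def test_topology_always_wild(self, square_hierarchy, table):
        specs = [p.parse_mutation("I4S")]
        mut = p.reweight_mutant(square_hierarchy, specs, table)
        assert set(mut.top.edges) == set(square_hierarchy.top.edges)


class TestResampling:
    SPECS = ["A1R", "A2R", "A3R", "I4R", "I5R", "I6R", "S7I", "S8I", "S9I", "T10I"]

    def specs(self):
        return [p.parse_mutation(s) for s in self.SPECS]

    def test_design_arithmetic_matches_stated_expectation(self):
        samples, size = p.suggest_resampling_design(10, 2.5, sample_size=5)
        assert (samples, size) == (5, 5)
        assert samples * size / 10 == 2.5

    def test_degenerate_single_full_sample(self, square_hierarchy, table):
        specs = self.specs()
        rep = p.mutation_resampling(
            square_hierarchy, specs, 1, len(specs), 0, table, "max_weighted_degree:Hydpthy"
        )
        full = p.mst_for_mutations(square_hierarchy, specs, table, "max_weighted_degree:Hydpthy")
        assert (rep.stats["sd_degree"] == 0).all()
        for v, deg in full.degrees.items():
            assert rep.stats.loc[v, "mean_degree"] == deg

    def test_same_seed_reproduces_report_byte_identically(self, square_hierarchy, table):
        specs = self.specs()
        reps = [
            p.mutation_resampling(
                square_hierarchy, specs, 5, 5, 7, table, "max_weighted_degree:Hydpthy"
            )
            for _ in range(2)
        ]
        assert reps[0].to_csv() == reps[1].to_csv()

    def test_sample_size_larger_than_pool_rejected(self, square_hierarchy, table):
        with pytest.raises(ValueError, match="sample size"):
            p.mutation_resampling(
                square_hierarchy, self.specs(), 2, 99, 0, table, "max_weighted_degree:Hydpthy"
            )

    def test_standard_error_shrinks_with_more_samples(self, square_hierarchy, table):
        specs = self.specs()
        se = []
        for samples in (8, 16, 32):
            rep = p.mutation_resampling(
                square_hierarchy, specs, samples, 5, 11, table, "max_weighted_degree:Hydpthy"
            )
            se.append(float(rep.stats["sd_degree"].mean()) / np.sqrt(samples))
        assert se[0] > se[1] > se[2] or (se[0] >= se[1] >= se[2] and se[2] < se[0])

    def test_stability_classification_threshold_semantics(self, square_hierarchy, table):
        rep = p.mutation_resampling(
            square_hierarchy, self.specs(), 12, 5, 3, table, "max_weighted_degree:Hydpthy"
        )
        cls = p.stability_classification(rep, tolerance=0.0)
        assert set(cls["stable"]) | set(cls["sensitive"]) == set(rep.stats.index)
        assert not (set(cls["stable"]) & set(cls["sensitive"]))
        for v in cls["sensitive"]:
            assert rep.stats.loc[v, "sd_degree"] > 0
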