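import numpy as np
import pytest

from oracles import exhaustive_max_modularity
from karyograph.alg import (ALGPartition, LinkageGraph, build_linkage_graph,
                            consensus_communities, modularity,
                            place_orthogroups, scenario_sweep)
from karyograph.io import Gene, GenomeAnnotation, OrthogroupTable


def two_triangle_graph():
    """Two unit-weight triangles joined by a single bridge edge."""
    edges = {(0, 1): 1, (1, 2): 1, (0, 2): 1,
             (3, 4): 1, (4, 5): 1, (3, 5): 1, (2, 3): 1}
    return LinkageGraph([f"n{i}" for i in range(6)], edges)


class TestPlacement:
    @pytest.fixture
    def ann(self):
        genes = [Gene("g1", "chr1", 0, 10), Gene("g2", "chr1", 20, 30),
                 Gene("g3", "chr2", 0, 10), Gene("g4", "chr2", 20, 30)]
        return GenomeAnnotation("S", genes)

    def test_plurality_wins(self, ann):
        t = OrthogroupTable(["S"], {"OG": {"S": ["g1", "g2", "g3"]}})
        pl = place_orthogroups(t, {"S": ann})
        assert pl["S"]["OG"] == "chr1"

    def test_tie_is_unplaced(self, ann):
        t = OrthogroupTable(["S"], {"OG": {"S": ["g1", "g3"]}})
        assert place_orthogroups(t, {"S": ann})["S"]["OG"] is None

    def test_single_copy_placed_on_its_chromosome(self, ann):
        t = OrthogroupTable(["S"], {"OG": {"S": ["g4"]}})
        assert place_orthogroups(t, {"S": ann})["S"]["OG"] == "chr2"

    def test_missing_gene_named_in_error(self, ann):
        t = OrthogroupTable(["S"], {"OG": {"S": ["ghost"]}})
        with pytest.raises(KeyError, match="ghost"):
            place_orthogroups(t, {"S": ann})


class TestLinkageGraph:
    def test_weight_counts_supporting_species(self):
        placements = {
            "S1": {"OG1": "c1", "OG2": "c1", "OG3": "c2"},
            "S2": {"OG1": "x", "OG2": "x", "OG3": "x"},
            "S3": {"OG1": "y", "OG2": "y", "OG3": "z"},
        }
        g = build_linkage_graph(placements, min_support=2)
        w = {tuple(sorted((g.nodes[i], g.nodes[j]))): v
             for (i, j), v in g.edges.items()}
        assert w[("OG1", "OG2")] == 3
        # OG1-OG3 supported only by S2 -> below min_support
        assert ("OG1", "OG3") not in w and ("OG2", "OG3") not in w

    def test_unplaced_species_contributes_nothing(self):
        placements = {
            "S1": {"OG1": "c", "OG2": "c"},
            "S2": {"OG1": None, "OG2": "c"},
        }
        g = build_linkage_graph(placements, min_support=1)
        assert list(g.edges.values()) == [1]

    def test_isolated_nodes_retained(self):
        placements = {"S1": {"OG1": "c1", "OG2": "c2"},
                      "S2": {"OG1": "c1", "OG2": "c3"}}
        g = build_linkage_graph(placements)
        assert g.n_nodes == 2 and g.n_edges == 0

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            build_linkage_graph({"S1": {"OG1": "c"}})


class TestModularity:
    def test_two_triangles_hand_value(self):
        g = two_triangle_graph()
        part = {f"n{i}": int(i >= 3) for i in range(6)}
        assert modularity(g, part) == pytest.approx(6 / 7 - 1 / 2, abs=1e-12)

    def test_two_triangles_is_exhaustive_maximum(self):
        g = two_triangle_graph()
        opt = exhaustive_max_modularity(6, {k: float(v)
                                            for k, v in g.edges.items()})
        assert opt == pytest.approx(6 / 7 - 1 / 2, abs=1e-12)

    def test_single_community_is_zero(self):
        g = two_triangle_graph()
        assert modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0)

    def test_triangle_singletons(self):
        g = LinkageGraph(["a", "b", "c"],
                         {(0, 1): 1, (1, 2): 1, (0, 2): 1})
        part = {"a": 0, "b": 1, "c": 2}
        assert modularity(g, part) == pytest.approx(-1 / 3)

    def test_missing_node_rejected(self):
        g = two_triangle_graph()
        with pytest.raises(KeyError):
            modularity(g, {"n0": 0})


class TestConsensus:
    def test_two_triangles_recovered_with_full_stability(self):
        g = two_triangle_graph()
        p = consensus_communities(g, n_runs=10, seed=1)
        groups = {}
        for n, lab in p.assignment.items():
            groups.setdefault(lab, set()).add(n)
        assert sorted(map(sorted, groups.values())) == \
            [["n0", "n1", "n2"], ["n3", "n4", "n5"]]
        assert p.stability == pytest.approx(1.0)
        assert p.modularity == pytest.approx(6 / 7 - 1 / 2)

    def test_edgeless_graph_gives_singletons(self):
        g = LinkageGraph(["a", "b", "c"], {})
        p = consensus_communities(g, n_runs=5, seed=0)
        assert len(set(p.assignment.values())) == 3
        assert p.modularity == 0.0

    def test_same_seed_same_partition(self):
        g = two_triangle_graph()
        a = consensus_communities(g, n_runs=8, seed=42)
        b = consensus_communities(g, n_runs=8, seed=42)
        assert a.assignment == b.assignment

    def test_node_order_invariance(self):
        edges = {(0, 1): 2, (1, 2): 2, (0, 2): 2, (3, 4): 2, (2, 3): 1}
        g1 = LinkageGraph(["a", "b", "c", "d", "e"], edges)
        perm = [4, 2, 0, 1, 3]  # same graph, permuted node insertion order
        names = ["a", "b", "c", "d", "e"]
        inv = {old: new for new, old in enumerate(perm)}
        g2 = LinkageGraph([names[i] for i in perm],
                          {tuple(sorted((inv[i], inv[j]))): w
                           for (i, j), w in edges.items()})
        p1 = consensus_communities(g1, n_runs=8, seed=3)
        p2 = consensus_communities(g2, n_runs=8, seed=3)
        grp = lambda p: sorted(sorted(m) for m in
                               ({} or p).members().values())
        assert grp(p1) == grp(p2)

    def test_n_runs_lower_bound(self):
        with pytest.raises(ValueError):
            consensus_communities(two_triangle_graph(), n_runs=1)

    def test_small_random_graphs_attain_exhaustive_optimum(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            n = int(rng.integers(3, 8))
            edges = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.5:
                        edges[(i, j)] = int(rng.integers(1, 4))
            g = LinkageGraph([f"v{k}" for k in range(n)], edges)
            opt = exhaustive_max_modularity(
                n, {k: float(v) for k, v in edges.items()})
            p = consensus_communities(g, n_runs=10, seed=trial)
            assert p.modularity == pytest.approx(opt, abs=1e-9)


class TestScenarioSweep:
    def planted_three_clique_graph(self):
        """Three 6-node cliques with single bridging edges."""
        edges = {}
        for c in range(3):
            base = 6 * c
            for i in range(6):
                for j in range(i + 1, 6):
                    edges[(base + i, base + j)] = 3
        edges[(5, 6)] = 1
        edges[(11, 12)] = 1
        return LinkageGraph([f"n{i}" for i in range(18)], edges)

    def test_planted_cliques_recovered(self):
        g = self.planted_three_clique_graph()
        parts = scenario_sweep(g, [0.5, 1.0, 2.0], n_runs=8, seed=2)
        assert parts[0].n_algs == 3

    def test_single_resolution_grid(self):
        g = two_triangle_graph()
        parts = scenario_sweep(g, [1.0], n_runs=6, seed=0)
        assert len(parts) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            scenario_sweep(two_triangle_graph(), [])

    def test_sorted_by_modularity(self):
        g = self.planted_three_clique_graph()
        parts = scenario_sweep(g, [0.2, 1.0, 5.0], n_runs=6, seed=1)
        qs = [p.modularity for p in parts]
        assert qs == sorted(qs, reverse=True)
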