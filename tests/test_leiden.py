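"""Leiden algorithm: quality functions, convergence guarantees, oracles."""

import numpy as np
import pandas as pd
import pytest

from nsnet.leiden import (
    Partition,
    QualityConfig,
    community_case_stats,
    cpm_quality,
    leiden,
    modularity,
    refine_and_aggregate,
)
from nsnet.ppi_network import build_network
from nsnet.synthetic_data import SimConfig, simulate_ppi

from _oracles import best_partition_bruteforce, modularity_of, random_graph_edges
from conftest import edge_df, make_network

TRIANGLE = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)]
TWO_TRIANGLES = TRIANGLE + [("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
# two triangles joined by one bridge
BARBELL = TWO_TRIANGLES + [("c", "x", 1.0)]


class TestModularity:
    def test_single_community_is_zero(self):
        net = make_network(TRIANGLE)
        assert modularity(net, {g: 0 for g in "abc"}) == pytest.approx(0.0)

    def test_triangle_singletons(self):
        # Q = 0 - 3 * (2/6)^2 = -1/3
        net = make_network(TRIANGLE)
        assert modularity(net, {"a": 0, "b": 1, "c": 2}) == pytest.approx(-1 / 3)

    def test_matches_independent_formula_on_random_partitions(self):
        rng = np.random.default_rng(7)
        nodes, edges = random_graph_edges(rng, 8, 0.5)
        net = make_network(edges, extra_nodes=nodes)
        for _ in range(10):
            labels = rng.integers(0, 3, size=len(nodes))
            part = dict(zip(nodes, (int(x) for x in labels)))
            blocks = [[n for n in nodes if part[n] == c] for c in set(labels)]
            blocks = [b for b in blocks if b]
            assert modularity(net, part) == pytest.approx(
                modularity_of(edges, nodes, blocks), abs=1e-12
            )

    def test_uncovered_node_rejected(self):
        net = make_network(TRIANGLE)
        with pytest.raises(ValueError, match="cover"):
            modularity(net, {"a": 0, "b": 0})

    def test_barbell_natural_split_is_global_optimum(self):
        nodes = list("abcxyz")
        best_q, best_blocks = best_partition_bruteforce(BARBELL, nodes)
        natural = modularity_of(BARBELL, nodes, [list("abc"), list("xyz")])
        assert natural == pytest.approx(best_q)

    def test_networkx_agrees(self):
        # independent cross-check of the weighted quality function
        import networkx as nx

        net = make_network(BARBELL)
        part = {g: (0 if g in "abc" else 1) for g in "abcxyz"}
        nx_q = nx.community.modularity(
            net.graph, [{"a", "b", "c"}, {"x", "y", "z"}], weight="weight"
        )
        assert modularity(net, part) == pytest.approx(nx_q, abs=1e-12)


class TestLeiden:
    def test_two_disjoint_triangles_give_two_communities(self):
        net = make_network(TWO_TRIANGLES)
        part = leiden(net, QualityConfig(seed=0))
        assert part.n_communities == 2
        comms = part.communities()
        assert sorted(map(sorted, comms.values())) == [list("abc"), list("xyz")]

    def test_edgeless_graph_all_singletons(self):
        net = make_network([], extra_nodes=list("abcd"))
        part = leiden(net, QualityConfig(seed=0))
        assert part.n_communities == 4

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            leiden(make_network([]))

    def test_quality_monotone_across_passes(self):
        cfg = SimConfig(seed=5, n_genes=60)
        edges, truth = simulate_ppi(cfg)
        net = build_network(edges, truth.genes, 0.0)
        part = leiden(net, QualityConfig(seed=5))
        diffs = np.diff(part.quality_history)
        assert (diffs >= -1e-12).all()
        assert part.quality == pytest.approx(modularity(net, part.membership))

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=2, n_genes=40)
        edges, truth = simulate_ppi(cfg)
        net = build_network(edges, truth.genes, 0.0)
        p1 = leiden(net, QualityConfig(seed=11))
        p2 = leiden(net, QualityConfig(seed=11))
        assert p1.membership == p2.membership

    def test_communities_induce_connected_subgraphs(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        for trial in range(10):
            nodes, edges = random_graph_edges(rng, 12, 0.25)
            net = make_network(edges, extra_nodes=nodes)
            part = leiden(net, QualityConfig(seed=trial))
            for members in part.communities().values():
                if len(members) == 1:
                    continue
                sub = net.graph.subgraph(members)
                assert nx.is_connected(sub), members

    def test_degree_zero_nodes_stay_singletons(self):
        net = make_network(TRIANGLE, extra_nodes=["iso1", "iso2"])
        part = leiden(net, QualityConfig(seed=0))
        assert part.membership["iso1"] != part.membership["iso2"]
        assert {part.membership["iso1"], part.membership["iso2"]} & {
            part.membership["a"]
        } == set()

    def test_partition_structure_invariant_to_relabeling(self):
        cfg = SimConfig(seed=9, n_genes=30)
        edges, truth = simulate_ppi(cfg)
        net = build_network(edges, truth.genes, 0.0)
        base = leiden(net, QualityConfig(seed=1))
        # relabel genes by reversing symbols and rebuild
        rename = {g: f"Z{i:03d}" for i, g in enumerate(reversed(truth.genes))}
        renamed = edges.assign(
            gene_a=edges.gene_a.map(rename), gene_b=edges.gene_b.map(rename)
        )
        net2 = build_network(renamed, rename.values(), 0.0)
        perm = leiden(net2, QualityConfig(seed=1))
        groups = lambda p, names: sorted(
            sorted(names[g] for g in m) for m in p.communities().values()
        )
        assert groups(base, rename) == groups(perm, {v: v for v in rename.values()})

    def test_matches_bruteforce_on_small_graphs(self):
        rng = np.random.default_rng(17)
        hits = 0
        for trial in range(20):
            n = int(rng.integers(4, 8))
            nodes, edges = random_graph_edges(rng, n, 0.5)
            net = make_network(edges, extra_nodes=nodes)
            part = leiden(net, QualityConfig(seed=trial))
            best_q, _ = best_partition_bruteforce(edges, nodes)
            if part.quality >= best_q - 1e-9:
                hits += 1
        assert hits >= 19

    def test_cpm_on_cliques(self):
        net = make_network(TWO_TRIANGLES)
        part = leiden(net, QualityConfig(quality="cpm", resolution=0.5, seed=0))
        assert part.n_communities == 2
        assert part.quality == pytest.approx(
            cpm_quality(net, part.membership, resolution=0.5)
        )

    def test_leidenalg_oracle_equivalence(self):
        """Independent implementation reaches the same quality and structure."""
        igraph = pytest.importorskip("igraph")
        leidenalg = pytest.importorskip("leidenalg")
        from sklearn.metrics import normalized_mutual_info_score

        cfg = SimConfig(seed=4, n_genes=60)
        edges, truth = simulate_ppi(cfg)
        net = build_network(edges, truth.genes, 0.0)
        mine = leiden(net, QualityConfig(seed=4))

        g = igraph.Graph.TupleList(
            ((a, b) for a, b, _ in net.edges()), directed=False
        )
        weights = [w for _, _, w in net.edges()]
        ref = leidenalg.find_partition(
            g, leidenalg.ModularityVertexPartition, weights=weights, seed=4
        )
        ref_memb = {g.vs[i]["name"]: ref.membership[i] for i in range(g.vcount())}
        for v in net.nodes:
            ref_memb.setdefault(v, max(ref.membership, default=0) + 1)
        ref_q = modularity(net, ref_memb)
        assert mine.quality >= ref_q - 1e-9
        names = sorted(net.nodes)
        nmi = normalized_mutual_info_score(
            [mine.membership[n] for n in names], [ref_memb[n] for n in names]
        )
        assert nmi >= 0.9


class TestRefineAggregate:
    def test_weight_conserved_and_two_node_aggregate(self):
        net = make_network(BARBELL)
        part = {g: (0 if g in "abc" else 1) for g in "abcxyz"}
        agg, agg_memb, gene_map = refine_and_aggregate(net, part, QualityConfig(seed=0))
        assert agg.total_weight == pytest.approx(net.total_weight())
        assert agg.n == 2
        assert sorted(agg_memb) == [0, 1]
        # each triangle collapses to one aggregated node
        assert len({gene_map[g] for g in "abc"}) == 1
        assert len({gene_map[g] for g in "xyz"}) == 1

    def test_all_singleton_partition_aggregates_to_input(self):
        net = make_network(TRIANGLE)
        part = {"a": 0, "b": 1, "c": 2}
        agg, _, _ = refine_and_aggregate(net, part, QualityConfig(seed=0))
        assert agg.n == net.n_nodes
        assert agg.total_weight == pytest.approx(net.total_weight())


class TestCommunityStats:
    @staticmethod
    def qv(rows):
        return pd.DataFrame(rows, columns=["variant_key", "gene", "consequence", "carriers"])

    def test_single_community_holds_all_cases(self):
        qv = self.qv(
            [("1:1:A:T", "a", "stop_gain", frozenset({"s1", "s2"})),
             ("1:2:A:T", "b", "frameshift", frozenset({"s3"}))]
        )
        stats = community_case_stats({"a": 0, "b": 0, "c": 0}, qv)
        assert stats.loc[0, "n_cases"] == 3
        assert stats.loc[0, "pct_of_network_cases"] == 100.0

    def test_case_in_two_communities_counted_in_both(self):
        qv = self.qv(
            [("1:1:A:T", "a", "stop_gain", frozenset({"s1"})),
             ("1:2:A:T", "b", "stop_gain", frozenset({"s1"}))]
        )
        stats = community_case_stats({"a": 0, "b": 1}, qv).set_index("community")
        assert stats.loc[0, "n_cases"] == 1
        assert stats.loc[1, "n_cases"] == 1
        assert stats.loc[0, "pct_of_network_cases"] == 100.0

    def test_missing_gene_raises_with_name(self):
        qv = self.qv([("1:1:A:T", "ghost", "stop_gain", frozenset({"s1"}))])
        with pytest.raises(ValueError, match="ghost"):
            community_case_stats({"a": 0}, qv)

    def test_gene_counts_partition_wide(self):
        qv = self.qv([("1:1:A:T", "a", "stop_gain", frozenset({"s1"}))])
        stats = community_case_stats({"a": 0, "b": 1}, qv)
        assert stats["n_genes"].sum() == 2
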