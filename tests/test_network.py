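import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hicap import network as nw


def typed_graph(edges, kinds):
    g = nx.Graph()
    for node, kind in kinds.items():
        g.add_node(node, kind=kind, chrom="chr1", start=0, end=100)
    for u, v in edges:
        types = tuple(sorted((kinds[u], kinds[v])))
        etype = {("p", "p"): "PP", ("e", "p"): "PE", ("e", "e"): "EE"}[types]
        g.add_edge(u, v, etype=etype, weight=6, distance=10_000.0)
    return g


def brute_force_motif_count(net, motif):
    """Oracle: enumerate node subsets, count non-induced embeddings up to
    automorphism by checking every injective kind-respecting mapping."""
    k = motif.number_of_nodes()
    motif_nodes = list(motif.nodes)
    count = 0
    for subset in itertools.combinations(net.nodes, k):
        seen = set()
        for perm in itertools.permutations(subset):
            mapping = dict(zip(motif_nodes, perm))
            if any(
                net.nodes[mapping[m]]["kind"] != motif.nodes[m]["kind"]
                for m in motif_nodes
            ):
                continue
            if all(net.has_edge(mapping[a], mapping[b]) for a, b in motif.edges):
                seen.add(frozenset((m, mapping[m]) for m in motif_nodes))
        # distinct embeddings on this subset = distinct mappings / automorphisms
        if seen:
            aut = sum(
                1
                for perm in itertools.permutations(motif_nodes)
                if all(
                    motif.nodes[a]["kind"] == motif.nodes[b]["kind"]
                    for a, b in zip(motif_nodes, perm)
                )
                and all(
                    motif.has_edge(perm[motif_nodes.index(a)], perm[motif_nodes.index(b)])
                    for a, b in motif.edges
                )
            )
            count += len(seen) // aut
    return count


def brute_force_max_cliques(net, node_type):
    nodes = [n for n, d in net.nodes(data=True) if d["kind"] == node_type]
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(net.has_edge(a, b) for a, b in itertools.combinations(subset, 2)):
                cliques.append(set(subset))
    maximal = [c for c in cliques if not any(c < other for other in cliques)]
    return sorted((tuple(sorted(c)) for c in maximal), key=lambda c: (-len(c), c))


def make_calls(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "type", "anchor", "partner", "gene_id",
            "anchor_chrom", "anchor_start", "anchor_end",
            "partner_chrom", "partner_start", "partner_end",
            "trans", "distance", "support_rep1", "support_rep2",
        ],
    )


class TestBuildNetwork:
    def test_pd_call_gives_pe_edge(self):
        calls = make_calls(
            [("PD", "P1", "chr1:5000-6000", "G1", "chr1", 0, 200, "chr1", 5000, 6000, False, 5400.0, 3, 4)]
        )
        net = nw.build_network(calls)
        assert net.number_of_nodes() == 2 and net.number_of_edges() == 1
        assert net.edges["P1", "chr1:5000-6000"]["etype"] == "PE"
        assert net.edges["P1", "chr1:5000-6000"]["weight"] == 7

    def test_pp_and_dd_types(self):
        calls = make_calls(
            [
                ("PP", "P1", "P2", "G1", "chr1", 0, 200, "chr1", 9000, 9200, False, 9000.0, 3, 3),
                ("DD", "chr1:1-2", "chr1:5-6", "", "chr1", 1, 2, "chr1", 5, 6, False, 4.0, 3, 3),
            ]
        )
        net = nw.build_network(calls)
        assert net.edges["P1", "P2"]["etype"] == "PP"
        assert net.edges["chr1:1-2", "chr1:5-6"]["etype"] == "EE"

    def test_duplicate_call_idempotent(self):
        row = ("PD", "P1", "chr1:5000-6000", "G1", "chr1", 0, 200, "chr1", 5000, 6000, False, 5400.0, 3, 3)
        net = nw.build_network(make_calls([row, row]))
        assert net.number_of_edges() == 1


class TestDegreeStats:
    def test_star(self):
        edges = [("P1", f"E{i}") for i in range(5)]
        kinds = {"P1": "p", **{f"E{i}": "e" for i in range(5)}}
        stats = nw.degree_stats(typed_graph(edges, kinds))
        assert stats["mean_enhancers_per_promoter"] == 5.0
        assert stats["mean_promoters_per_enhancer"] == 1.0

    def test_empty(self):
        stats = nw.degree_stats(nx.Graph())
        assert np.isnan(stats["mean_promoters_per_enhancer"])

    def test_matches_hand_count_on_small_graph(self):
        rng = np.random.default_rng(0)
        kinds = {f"N{i}": ("p" if i % 2 else "e") for i in range(10)}
        nodes = list(kinds)
        edges = set()
        while len(edges) < 12:
            u, v = rng.choice(nodes, 2, replace=False)
            edges.add(tuple(sorted((u, v))))
        net = typed_graph(sorted(edges), kinds)
        stats = nw.degree_stats(net)
        for node, kind in kinds.items():
            other = "e" if kind == "p" else "p"
            expected = sum(1 for n in net.neighbors(node) if kinds[n] == other)
            dist = (
                stats["enhancers_per_promoter"] if kind == "p" else stats["promoters_per_enhancer"]
            )
            assert expected in dist  # weak membership; means checked below
        p_deg = [sum(1 for n in net.neighbors(x) if kinds[n] == "e") for x in nodes if kinds[x] == "p"]
        assert stats["mean_enhancers_per_promoter"] == pytest.approx(np.mean(p_deg))


class TestRandomizeEdges:
    def big_mixed_graph(self, seed=0):
        rng = np.random.default_rng(seed)
        kinds = {f"P{i}": "p" for i in range(15)} | {f"E{i}": "e" for i in range(15)}
        nodes = list(kinds)
        edges = set()
        while len(edges) < 60:
            u, v = rng.choice(nodes, 2, replace=False)
            edges.add(tuple(sorted((u, v))))
        return typed_graph(sorted(edges), kinds), kinds

    def class_degrees(self, net):
        out = {}
        for node in net.nodes:
            per_class = {"PP": 0, "PE": 0, "EE": 0}
            for nbr in net.neighbors(node):
                per_class[net.edges[node, nbr]["etype"]] += 1
            out[node] = per_class
        return out

    def test_per_class_degrees_preserved_exactly(self):
        net, _ = self.big_mixed_graph()
        before = self.class_degrees(net)
        for rand in nw.randomize_edges(net, n_rounds=5, seed=1):
            assert self.class_degrees(rand) == before
            assert rand.number_of_edges() == net.number_of_edges()
            assert not any(u == v for u, v in rand.edges)

    def test_rewiring_changes_edges(self):
        net, _ = self.big_mixed_graph()
        rand = nw.randomize_edges(net, n_rounds=1, seed=2)[0]
        assert set(map(frozenset, rand.edges)) != set(map(frozenset, net.edges))

    def test_single_edge_class_unchanged_with_warning(self):
        net = typed_graph([("P1", "P2")], {"P1": "p", "P2": "p"})
        with pytest.warns(UserWarning):
            rand = nw.randomize_edges(net, n_rounds=1, seed=0)[0]
        assert set(map(frozenset, rand.edges)) == set(map(frozenset, net.edges))

    def test_seed_reproducible(self):
        net, _ = self.big_mixed_graph()
        a = nw.randomize_edges(net, n_rounds=3, seed=9)
        b = nw.randomize_edges(net, n_rounds=3, seed=9)
        for ga, gb in zip(a, b):
            assert set(map(frozenset, ga.edges)) == set(map(frozenset, gb.edges))


class TestCountMotifs:
    def test_triangle_example(self):
        # promoters A,B joined to each other and both to enhancer E
        net = typed_graph(
            [("A", "B"), ("A", "E"), ("B", "E")], {"A": "p", "B": "p", "E": "e"}
        )
        counts = nw.count_motifs(net).set_index("motif")["observed"]
        assert counts["p-p"] == 1
        assert counts["p-e"] == 2
        assert counts["p-e-p"] == 1
        assert counts["p-p-e-triangle"] == 1
        assert counts["e-p-e"] == 0
        assert counts["p-clique3"] == 0

    def test_empty_network(self):
        counts = nw.count_motifs(nx.Graph())
        assert (counts["observed"] == 0).all()

    def test_absent_in_background_is_inf(self):
        net = typed_graph(
            [("A", "B"), ("A", "E"), ("B", "E")], {"A": "p", "B": "p", "E": "e"}
        )
        # background without the PP edge can never contain the triangle
        bg = typed_graph([("A", "E"), ("B", "E")], {"A": "p", "B": "p", "E": "e"})
        counts = nw.count_motifs(net, backgrounds=[bg]).set_index("motif")
        assert counts.loc["p-p-e-triangle", "enrichment"] == "~inf"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        kinds = {f"N{i}": ("p" if rng.random() < 0.5 else "e") for i in range(n)}
        edges = [
            (f"N{i}", f"N{j}")
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.3
        ]
        net = typed_graph(edges, kinds)
        counts = nw.count_motifs(net).set_index("motif")["observed"]
        for name, motif in nw.default_motif_catalog().items():
            assert counts[name] == brute_force_motif_count(net, motif), name


class TestMaxCliques:
    def test_k4(self):
        nodes = ["A", "B", "C", "D"]
        edges = list(itertools.combinations(nodes, 2))
        net = typed_graph(edges, {n: "p" for n in nodes})
        cliques = nw.max_cliques(net, "p")
        assert len(cliques[0]) == 4

    def test_path_of_three(self):
        net = typed_graph([("A", "B"), ("B", "C")], {n: "p" for n in "ABC"})
        cliques = nw.max_cliques(net, "p")
        assert len(cliques[0]) == 2

    def test_only_requested_type_considered(self):
        net = typed_graph(
            [("A", "B"), ("A", "E"), ("B", "E")], {"A": "p", "B": "p", "E": "e"}
        )
        assert len(nw.max_cliques(net, "p")[0]) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 11
        kinds = {f"N{i}": "p" for i in range(n)}
        edges = [
            (f"N{i}", f"N{j}")
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.4
        ]
        net = typed_graph(edges, kinds)
        assert [tuple(c) for c in nw.max_cliques(net, "p")] == brute_force_max_cliques(net, "p")


class TestSameTFDegree:
    def ee_graph(self):
        # E0..E3 form a clique; E4..E9 isolated (EE-wise)
        nodes = {f"E{i}": "e" for i in range(10)}
        edges = list(itertools.combinations(["E0", "E1", "E2", "E3"], 2))
        g = typed_graph(edges, nodes)
        for i, node in enumerate(nodes):
            g.nodes[node]["start"] = i * 1000
            g.nodes[node]["end"] = i * 1000 + 100
        return g

    def peaks_for(self, nodes):
        return pd.DataFrame(
            [("chr1", int(n[1:]) * 1000, int(n[1:]) * 1000 + 100) for n in nodes],
            columns=["chrom", "start", "end"],
        )

    def test_clique_selection_significant(self):
        net = self.ee_graph()
        peaks = {"TF1": self.peaks_for(["E0", "E1", "E2", "E3"])}
        res = nw.same_tf_degree(net, peaks, n_rand=200, seed=0)
        assert res["mean_degree"].iloc[0] == 3.0
        assert res["p"].iloc[0] <= 0.05

    def test_all_bound_p_near_one(self):
        net = self.ee_graph()
        peaks = {"TF1": self.peaks_for([f"E{i}" for i in range(10)])}
        res = nw.same_tf_degree(net, peaks, n_rand=100, seed=0)
        assert res["p"].iloc[0] == 1.0

    def test_under_two_bound_flagged(self):
        net = self.ee_graph()
        peaks = {"TF1": self.peaks_for(["E0"])}
        res = nw.same_tf_degree(net, peaks, n_rand=10, seed=0)
        assert np.isnan(res["p"].iloc[0])

    def test_seed_reproducible(self):
        net = self.ee_graph()
        peaks = {"TF1": self.peaks_for(["E0", "E1", "E4"])}
        a = nw.same_tf_degree(net, peaks, n_rand=100, seed=3)
        b = nw.same_tf_degree(net, peaks, n_rand=100, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestGoPairSharing:
    def shared_enhancer_net(self):
        # P1-P2 direct PP; P3,P4 share enhancer E1
        return typed_graph(
            [("P1", "P2"), ("P3", "E1"), ("P4", "E1"), ("P5", "E2")],
            {"P1": "p", "P2": "p", "P3": "p", "P4": "p", "P5": "p", "E1": "e", "E2": "e"},
        )

    def promoter_gene(self):
        return {f"P{i}": f"G{i}" for i in range(1, 6)}

    def test_connected_pairs(self):
        pairs = nw._connected_gene_pairs(self.shared_enhancer_net(), self.promoter_gene())
        assert pairs == {frozenset(("G1", "G2")), frozenset(("G3", "G4"))}

    def test_unconnected_term_p_one(self):
        go = pd.DataFrame(
            [("G1", "T_conn"), ("G2", "T_conn"), ("G1", "T_lonely"), ("G5", "T_lonely")],
            columns=["gene_id", "term"],
        )
        res = nw.go_pair_sharing(
            self.shared_enhancer_net(), go, self.promoter_gene(), n_rand=50, seed=0
        ).set_index("term")
        assert res.loc["T_lonely", "pair_count"] == 0
        assert res.loc["T_lonely", "p"] == 1.0

    def test_p_floor(self):
        go = pd.DataFrame([("G1", "T"), ("G2", "T")], columns=["gene_id", "term"])
        res = nw.go_pair_sharing(
            self.shared_enhancer_net(), go, self.promoter_gene(), n_rand=1000, seed=0
        )
        assert res["p"].min() >= 0.001

    def test_null_pvalues_roughly_uniform(self):
        """Random annotations on null-drawn graphs -> mean p in [0.45, 0.55]
        over 200 terms.

        Per-term p-values within one graph are correlated (they share the
        observed instance) and the paper's "or one less" correction biases
        small-count p upward, so the 200 terms are spread over ten
        independent instances with per-term pair counts large enough
        (~190) for the correction to be a small perturbation."""
        rng = np.random.default_rng(3)
        n_p, n_e, n_edges = 200, 60, 1200
        all_p = []
        for instance in range(10):
            kinds = {f"P{i}": "p" for i in range(n_p)} | {f"E{i}": "e" for i in range(n_e)}
            nodes = list(kinds)
            edges = set()
            while len(edges) < n_edges:
                u, v = rng.choice(nodes, 2, replace=False)
                edges.add(tuple(sorted((u, v))))
            # draw the observed graph from the rewiring null itself so only
            # the annotation shuffle is random
            el = nw._swap_edge_list(sorted(edges), rng, 10 * n_edges)
            net = typed_graph(el, kinds)
            promoter_gene = {f"P{i}": f"G{i}" for i in range(n_p)}
            genes = list(promoter_gene.values())
            rows = []
            for t in range(20):
                for g in rng.choice(genes, size=60, replace=False):
                    rows.append((g, f"T{t}"))
            go = pd.DataFrame(rows, columns=["gene_id", "term"])
            res = nw.go_pair_sharing(net, go, promoter_gene, n_rand=60, seed=instance)
            informative = res[res["pair_count"] > 0]
            all_p.extend(informative["p"].tolist())
            assert res["p"].between(0.001, 1.0).all()
        assert len(all_p) == 200
        assert 0.45 <= np.mean(all_p) <= 0.55


class TestSupportVsSharedEnhancers:
    def grouped_net(self, rng, n_pp=120, effect=0.0):
        """PP edges in one distance bin / degree group with shared-enhancer
        strata 0/1/2; support optionally shifted upward by `effect` per
        shared enhancer."""
        g = nx.Graph()
        for i in range(n_pp):
            p1, p2 = f"A{i}", f"B{i}"
            shared = i % 3
            for node in (p1, p2):
                g.add_node(node, kind="p", chrom="chr1", start=0, end=100)
            support = int(rng.poisson(8) + effect * shared)
            g.add_edge(p1, p2, etype="PP", weight=support, distance=1500.0)
            for s in range(shared):
                e = f"E{i}_{s}"
                g.add_node(e, kind="e", chrom="chr1", start=0, end=100)
                g.add_edge(p1, e, etype="PE", weight=3, distance=1000.0)
                g.add_edge(p2, e, etype="PE", weight=3, distance=1000.0)
            # decouple total degree from shared count with private enhancers
            for node in (p1, p2):
                for s in range(int(rng.integers(0, 3))):
                    e = f"X{node}_{s}"
                    g.add_node(e, kind="e", chrom="chr1", start=0, end=100)
                    g.add_edge(node, e, etype="PE", weight=3, distance=1000.0)
        return g

    def test_single_group_combined_equals_group_p(self):
        rng = np.random.default_rng(0)
        net = self.grouped_net(rng, n_pp=60, effect=5.0)
        res = nw.support_vs_shared_enhancers(net)
        groups = res["groups"]
        if len(groups) == 1:
            from scipy import stats as sps

            z = groups["z"].iloc[0]
            assert res["combined_p"] == pytest.approx(2 * sps.norm.sf(abs(z)))

    def test_positive_effect_detected(self):
        rng = np.random.default_rng(1)
        net = self.grouped_net(rng, n_pp=150, effect=6.0)
        res = nw.support_vs_shared_enhancers(net)
        assert res["n_groups"] >= 1
        assert res["combined_z"] > 0
        assert res["combined_p"] < 0.01

    def test_null_not_significant(self):
        # identical support distributions across strata, many seeds
        pvals = []
        for seed in range(8):
            rng = np.random.default_rng(1000 + seed)
            net = self.grouped_net(rng, n_pp=150, effect=0.0)
            pvals.append(nw.support_vs_shared_enhancers(net)["combined_p"])
        assert np.mean(np.array(pvals) < 0.05) <= 0.25

    def test_no_pp_edges_rejected(self):
        net = typed_graph([("P1", "E1")], {"P1": "p", "E1": "e"})
        with pytest.raises(ValueError):
            nw.support_vs_shared_enhancers(net)


class TestOnSimulatedCalls(object):
    def test_network_from_pipeline_calls(self, sim_calls):
        net = nw.build_network(sim_calls["all_calls"])
        stats = nw.degree_stats(net)
        assert stats["mean_promoters_per_enhancer"] >= 1.0
        assert stats["mean_enhancers_per_promoter"] >= 1.0
        backgrounds = nw.randomize_edges(net, n_rounds=3, seed=0)
        counts = nw.count_motifs(net, backgrounds=backgrounds).set_index("motif")
        # dimer counts are degree-determined, hence identical in backgrounds
        assert counts.loc["p-e", "observed"] == counts.loc["p-e", "background_mean"]
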