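"""Typed promoter/enhancer interaction networks: motifs, cliques,
degree-preserving randomization and associated permutation statistics."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import isomorphism
from scipy import stats as sps

from .intervals import GenomicIntervals
from .stats import bh_adjust, permutation_pvalue, stouffer

__all__ = [
    "build_network",
    "degree_stats",
    "randomize_edges",
    "default_motif_catalog",
    "count_motifs",
    "max_cliques",
    "same_tf_degree",
    "go_pair_sharing",
    "support_vs_shared_enhancers",
]

EDGE_TYPE_BY_KINDS = {("p", "p"): "PP", ("e", "p"): "PE", ("e", "e"): "EE"}


def _edge_type(net: nx.Graph, u, v) -> str:
    kinds = tuple(sorted((net.nodes[u]["kind"], net.nodes[v]["kind"])))
    return EDGE_TYPE_BY_KINDS[kinds]


def build_network(calls: pd.DataFrame) -> nx.Graph:
    """Graph with promoter ('p') and enhancer ('e') nodes from called
    interactions. PD calls give PE edges, PP calls PP edges, DD calls EE
    edges; edge weight is the summed per-replicate read support. Re-adding
    an identical call is idempotent."""
    sup_cols = [c for c in calls.columns if c.startswith("support_")]
    net = nx.Graph()
    for row in calls.itertuples(index=False):
        weight = int(sum(getattr(row, c) for c in sup_cols))
        if row.type == "PP":
            u, v = row.anchor, row.partner
            net.add_node(u, kind="p", chrom=row.anchor_chrom, start=int(row.anchor_start), end=int(row.anchor_end))
            net.add_node(v, kind="p", chrom=row.partner_chrom, start=int(row.partner_start), end=int(row.partner_end))
        elif row.type == "PD":
            u, v = row.anchor, row.partner
            net.add_node(u, kind="p", chrom=row.anchor_chrom, start=int(row.anchor_start), end=int(row.anchor_end))
            net.add_node(v, kind="e", chrom=row.partner_chrom, start=int(row.partner_start), end=int(row.partner_end))
        else:  # DD
            u, v = row.anchor, row.partner
            net.add_node(u, kind="e", chrom=row.anchor_chrom, start=int(row.anchor_start), end=int(row.anchor_end))
            net.add_node(v, kind="e", chrom=row.partner_chrom, start=int(row.partner_start), end=int(row.partner_end))
        if u == v:
            continue
        distance = None if row.trans else float(row.distance)
        net.add_edge(u, v, etype=_edge_type(net, u, v), weight=weight, distance=distance)
    return net


def degree_stats(net: nx.Graph) -> dict:
    """Cross-type degree distributions: promoter neighbours per enhancer and
    enhancer neighbours per promoter."""
    promoter_deg = []
    enhancer_deg = []
    for node, data in net.nodes(data=True):
        nbr_kinds = [net.nodes[n]["kind"] for n in net.neighbors(node)]
        if data["kind"] == "e":
            enhancer_deg.append(sum(k == "p" for k in nbr_kinds))
        else:
            promoter_deg.append(sum(k == "e" for k in nbr_kinds))
    return {
        "promoters_per_enhancer": np.asarray(enhancer_deg, dtype=int),
        "enhancers_per_promoter": np.asarray(promoter_deg, dtype=int),
        "mean_promoters_per_enhancer": float(np.mean(enhancer_deg)) if enhancer_deg else float("nan"),
        "mean_enhancers_per_promoter": float(np.mean(promoter_deg)) if promoter_deg else float("nan"),
    }


def _swap_edges(
    net: nx.Graph, edges: list[tuple], rng: np.random.Generator, bipartite: bool
) -> None:
    """In-place degree-preserving double-edge swaps restricted to `edges`.

    For bipartite (PE) edges the first element is always the promoter, so a
    swap exchanges the enhancer endpoints; for within-type edges the swap
    orientation is random. Swaps creating self-loops or multi-edges are
    rejected.
    """
    n_edges = len(edges)
    if n_edges < 2:
        return
    n_attempts = 10 * n_edges
    idx = rng.integers(0, n_edges, size=(n_attempts, 2))
    coins = rng.random(n_attempts)
    for k in range(n_attempts):
        i, j = idx[k]
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if bipartite or coins[k] < 0.5:
            new1, new2 = (a, d), (c, b)
        else:
            new1, new2 = (a, c), (b, d)
        (p, q), (r, s) = new1, new2
        if p == q or r == s:
            continue
        if net.has_edge(p, q) or net.has_edge(r, s):
            continue
        if (p, q) == (s, r) or (p, q) == (r, s):
            continue
        attrs1 = net.edges[edges[i]]
        attrs2 = net.edges[edges[j]]
        net.remove_edge(*edges[i])
        net.remove_edge(*edges[j])
        net.add_edge(p, q, **{**attrs1, "etype": _edge_type(net, p, q), "distance": None})
        net.add_edge(r, s, **{**attrs2, "etype": _edge_type(net, r, s), "distance": None})
        edges[i], edges[j] = new1, new2


def _randomize_once(net: nx.Graph, rng: np.random.Generator, per_class: bool) -> nx.Graph:
    rand = net.copy()
    if per_class:
        for etype in ("PP", "PE", "EE"):
            edges = []
            for u, v, data in rand.edges(data=True):
                if data["etype"] != etype:
                    continue
                if etype == "PE" and rand.nodes[u]["kind"] != "p":
                    u, v = v, u
                edges.append((u, v))
            if len(edges) == 1:
                continue
            _swap_edges(rand, edges, rng, bipartite=(etype == "PE"))
    else:
        edges = [(u, v) for u, v in rand.edges()]
        _swap_edges(rand, edges, rng, bipartite=False)
    return rand


def randomize_edges(
    net: nx.Graph, n_rounds: int = 5, seed: int = 0, per_class: bool = True
) -> list[nx.Graph]:
    """Degree-preserving randomizations of the network.

    With ``per_class=True`` (the motif background) PP, PE and EE edges are
    rewired separately so every node keeps its degree within each edge
    class; with ``per_class=False`` all edges are rewired jointly (the GO
    permutation null). Classes with a single edge are left unchanged with a
    warning.
    """
    rng = np.random.default_rng(seed)
    if per_class:
        for etype in ("PP", "PE", "EE"):
            n = sum(1 for _, _, d in net.edges(data=True) if d["etype"] == etype)
            if n == 1:
                warnings.warn(f"edge class {etype} has a single edge; left unchanged")
    return [_randomize_once(net, rng, per_class) for _ in range(n_rounds)]


def _motif(edges: list[tuple[str, str]], kinds: Mapping[str, str]) -> nx.Graph:
    g = nx.Graph()
    for node, kind in kinds.items():
        g.add_node(node, kind=kind)
    g.add_edges_from(edges)
    return g


def default_motif_catalog() -> dict[str, nx.Graph]:
    """Named typed subgraphs: dimers, open 3-node paths, the mixed triangle
    and 3-cliques of each type."""
    return {
        "p-p": _motif([("a", "b")], {"a": "p", "b": "p"}),
        "p-e": _motif([("a", "b")], {"a": "p", "b": "e"}),
        "e-e": _motif([("a", "b")], {"a": "e", "b": "e"}),
        "p-e-p": _motif([("a", "x"), ("b", "x")], {"a": "p", "b": "p", "x": "e"}),
        "e-p-e": _motif([("a", "x"), ("b", "x")], {"a": "e", "b": "e", "x": "p"}),
        "p-p-e-triangle": _motif(
            [("a", "b"), ("a", "x"), ("b", "x")], {"a": "p", "b": "p", "x": "e"}
        ),
        "p-clique3": _motif(
            [("a", "b"), ("a", "c"), ("b", "c")], {"a": "p", "b": "p", "c": "p"}
        ),
        "e-clique3": _motif(
            [("a", "b"), ("a", "c"), ("b", "c")], {"a": "e", "b": "e", "c": "e"}
        ),
    }


def _kind_match(host_attrs: dict, motif_attrs: dict) -> bool:
    return host_attrs["kind"] == motif_attrs["kind"]


def _n_automorphisms(motif: nx.Graph) -> int:
    gm = isomorphism.GraphMatcher(motif, motif, node_match=_kind_match)
    return sum(1 for _ in gm.isomorphisms_iter())


def _count_embeddings(net: nx.Graph, motif: nx.Graph) -> tuple[int, set, set]:
    """Non-induced embeddings of `motif` in `net` up to motif automorphism,
    plus the unique promoter and enhancer nodes participating."""
    gm = isomorphism.GraphMatcher(net, motif, node_match=_kind_match)
    n_monos = 0
    promoters: set = set()
    enhancers: set = set()
    for mapping in gm.subgraph_monomorphisms_iter():
        n_monos += 1
        for host_node in mapping:
            if net.nodes[host_node]["kind"] == "p":
                promoters.add(host_node)
            else:
                enhancers.add(host_node)
    n_aut = _n_automorphisms(motif)
    return n_monos // n_aut, promoters, enhancers


def count_motifs(
    net: nx.Graph,
    motif_catalog: Mapping[str, nx.Graph] | None = None,
    backgrounds: Sequence[nx.Graph] | None = None,
) -> pd.DataFrame:
    """Count typed-motif embeddings and, when backgrounds are given,
    enrichment against their mean. Motifs absent from every background but
    present observed get "~inf" enrichment."""
    catalog = motif_catalog if motif_catalog is not None else default_motif_catalog()
    rows = []
    for name, motif in catalog.items():
        observed, promoters, enhancers = _count_embeddings(net, motif)
        rec: dict = {
            "motif": name,
            "observed": observed,
            "unique_promoters": len(promoters),
            "unique_enhancers": len(enhancers),
        }
        if backgrounds is not None:
            bg_counts = [_count_embeddings(bg, motif)[0] for bg in backgrounds]
            bg_mean = float(np.mean(bg_counts)) if bg_counts else 0.0
            rec["background_mean"] = bg_mean
            if bg_mean == 0.0:
                rec["enrichment"] = "~inf" if observed > 0 else "0"
            else:
                rec["enrichment"] = f"{observed / bg_mean:.4g}"
        rows.append(rec)
    return pd.DataFrame(rows)


def max_cliques(net: nx.Graph, node_type: str) -> list[list]:
    """All maximal cliques of the subgraph induced on `node_type` nodes,
    using only same-type edges; sorted largest-first."""
    nodes = [n for n, d in net.nodes(data=True) if d["kind"] == node_type]
    sub = net.subgraph(nodes)
    cliques = [sorted(c) for c in nx.find_cliques(sub)] if len(nodes) else []
    return sorted(cliques, key=lambda c: (-len(c), c))


def _enhancer_subgraph(net: nx.Graph) -> nx.Graph:
    nodes = [n for n, d in net.nodes(data=True) if d["kind"] == "e"]
    return net.subgraph(nodes)


def same_tf_degree(
    net: nx.Graph,
    tf_peaks: Mapping[str, pd.DataFrame],
    n_rand: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean degree inside the enhancer-only subnetwork restricted to
    enhancers bound by each TF, with an empirical p against random
    equal-size enhancer selections (floored at 1/n_rand)."""
    rng = np.random.default_rng(seed)
    esub = _enhancer_subgraph(net)
    enh_nodes = list(esub.nodes)
    coords = pd.DataFrame(
        [
            {"node": n, "chrom": esub.nodes[n]["chrom"], "start": esub.nodes[n]["start"], "end": esub.nodes[n]["end"]}
            for n in enh_nodes
        ]
    )
    rows = []
    for tf, peaks in tf_peaks.items():
        if len(enh_nodes) == 0:
            rows.append({"tf": tf, "n_bound": 0, "mean_degree": float("nan"), "p": float("nan")})
            continue
        index = GenomicIntervals(peaks)
        bound = [
            row.node
            for row in coords.itertuples(index=False)
            if index.overlaps(str(row.chrom), int(row.start), int(row.end))
        ]
        if len(bound) < 2:
            rows.append({"tf": tf, "n_bound": len(bound), "mean_degree": float("nan"), "p": float("nan")})
            continue
        sub = esub.subgraph(bound)
        observed = float(np.mean([sub.degree(n) for n in bound]))
        n_extreme = 0
        k = len(bound)
        for _ in range(n_rand):
            sel = rng.choice(len(enh_nodes), size=k, replace=False)
            rnd_nodes = [enh_nodes[i] for i in sel]
            rnd_sub = esub.subgraph(rnd_nodes)
            if float(np.mean([rnd_sub.degree(n) for n in rnd_nodes])) >= observed:
                n_extreme += 1
        rows.append(
            {
                "tf": tf,
                "n_bound": k,
                "mean_degree": observed,
                "p": permutation_pvalue(n_extreme, n_rand),
            }
        )
    return pd.DataFrame(rows)


def _pairs_from_edges(
    edges: list[tuple], kinds: Mapping[str, str], promoter_gene: Mapping[str, str]
) -> set[frozenset]:
    """Gene pairs joined by a PP edge or sharing an enhancer neighbour."""
    pairs: set[frozenset] = set()
    enh_nbrs: dict[str, set[str]] = {}
    for u, v in edges:
        ku, kv = kinds[u], kinds[v]
        if ku == "p" and kv == "p":
            gu, gv = promoter_gene.get(u), promoter_gene.get(v)
            if gu and gv and gu != gv:
                pairs.add(frozenset((gu, gv)))
        elif ku != kv:
            p, e = (u, v) if ku == "p" else (v, u)
            if p in promoter_gene:
                enh_nbrs.setdefault(e, set()).add(promoter_gene[p])
    for nbr_genes in enh_nbrs.values():
        genes = sorted(nbr_genes)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                pairs.add(frozenset((genes[i], genes[j])))
    return pairs


def _connected_gene_pairs(net: nx.Graph, promoter_gene: Mapping[str, str]) -> set[frozenset]:
    kinds = {n: d["kind"] for n, d in net.nodes(data=True)}
    return _pairs_from_edges(list(net.edges()), kinds, promoter_gene)


def _swap_edge_list(
    edges: list[tuple], rng: np.random.Generator, n_attempts: int
) -> list[tuple]:
    """Joint degree-preserving double-edge swaps on a plain edge list."""
    edges = list(edges)
    n_edges = len(edges)
    if n_edges < 2:
        return edges
    # integer-encode nodes; an undirected edge key is lo * n_nodes + hi
    nodes = sorted({n for e in edges for n in e})
    node_id = {n: i for i, n in enumerate(nodes)}
    n_nodes = len(nodes)

    def key(u: int, v: int) -> int:
        return u * n_nodes + v if u < v else v * n_nodes + u

    enc = [(node_id[a], node_id[b]) for a, b in edges]
    present = {key(a, b) for a, b in enc}
    idx = rng.integers(0, n_edges, size=(n_attempts, 2))
    coins = rng.random(n_attempts)
    for k in range(n_attempts):
        i, j = idx[k]
        if i == j:
            continue
        a, b = enc[i]
        c, d = enc[j]
        if coins[k] < 0.5:
            p, q, r, s = a, d, c, b
        else:
            p, q, r, s = a, c, b, d
        if p == q or r == s:
            continue
        k1, k2 = key(p, q), key(r, s)
        if k1 == k2 or k1 in present or k2 in present:
            continue
        present.discard(key(a, b))
        present.discard(key(c, d))
        present.add(k1)
        present.add(k2)
        enc[i] = (p, q)
        enc[j] = (r, s)
    return [(nodes[a], nodes[b]) for a, b in enc]


def go_pair_sharing(
    net: nx.Graph,
    go_table: pd.DataFrame,
    promoter_gene: Mapping[str, str],
    n_rand: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per GO term: connected gene pairs sharing the term, against a null
    that jointly rewires all interactions (degree-preserving) n_rand times.

    p = (#randomizations with >= observed-1 pairs) / n_rand, floored at
    1/n_rand; Benjamini-Hochberg adjusted across terms.
    """
    rng = np.random.default_rng(seed)
    terms = sorted({str(t) for t in go_table["term"]})
    term_index = {t: i for i, t in enumerate(terms)}
    genes = sorted({str(g) for g in go_table["gene_id"]} | set(promoter_gene.values()))
    gene_index = {g: i for i, g in enumerate(genes)}
    annot = np.zeros((len(genes), len(terms)), dtype=bool)
    for g, t in zip(go_table["gene_id"], go_table["term"]):
        annot[gene_index[str(g)], term_index[str(t)]] = True

    def per_term(pairs: set[frozenset]) -> np.ndarray:
        if not pairs:
            return np.zeros(len(terms), dtype=int)
        ia, ib = zip(*((gene_index[a], gene_index[b]) for a, b in map(tuple, pairs)))
        return (annot[list(ia)] & annot[list(ib)]).sum(axis=0)

    kinds = {n: d["kind"] for n, d in net.nodes(data=True)}
    edge_list = list(net.edges())
    observed = per_term(_pairs_from_edges(edge_list, kinds, promoter_gene))
    exceed = np.zeros(len(terms), dtype=int)
    threshold = np.maximum(observed - 1, 0)
    n_attempts = 10 * len(edge_list)
    for _ in range(n_rand):
        rand_edges = _swap_edge_list(edge_list, rng, n_attempts)
        rand_counts = per_term(_pairs_from_edges(rand_edges, kinds, promoter_gene))
        exceed += rand_counts >= threshold
    pvals = [
        permutation_pvalue(int(e), n_rand) if obs > 0 else 1.0
        for e, obs in zip(exceed, observed)
    ]
    fdr = bh_adjust(pvals)
    return pd.DataFrame(
        {"term": terms, "pair_count": observed.astype(int), "p": pvals, "fdr": fdr}
    )


DEFAULT_DISTANCE_BINS = [
    (1000, 2000),
    (2000, 4000),
    (4000, 8000),
    (8000, 16000),
    (16000, 32000),
    (32000, 64000),
    (64000, 128000),
]


def support_vs_shared_enhancers(
    net: nx.Graph,
    distance_bins: Sequence[tuple[int, int]] = tuple(DEFAULT_DISTANCE_BINS),
    degree_cap: int = 20,
    min_per_stratum: int = 2,
) -> dict:
    """Is PP read support higher when the promoter pair also shares
    enhancers?

    PP edges are grouped by distance bin and by the promoters' summed total
    degree (capped: >= degree_cap pools into one terminal group). Within a
    group, one-tailed Wilcoxon rank-sum tests compare read support between
    shared-enhancer strata (0 vs 1 and 1 vs 2+, higher stratum expected
    larger); z-scores combine across groups by Stouffer and the combined p
    is two-tailed. Groups with under-filled strata are skipped and logged.
    """
    records = []
    for u, v, data in net.edges(data=True):
        if data["etype"] != "PP" or data.get("distance") is None:
            continue
        shared = sum(
            1
            for n in set(net.neighbors(u)) & set(net.neighbors(v))
            if net.nodes[n]["kind"] == "e"
        )
        records.append(
            {
                "support": data["weight"],
                "distance": data["distance"],
                "degree_sum": net.degree(u) + net.degree(v),
                "shared": shared,
            }
        )
    frame = pd.DataFrame(records)
    if frame.empty:
        raise ValueError("no cis PP edges")
    frame["stratum"] = np.where(frame["shared"] >= 2, "2+", frame["shared"].astype(str))
    frame["degree_group"] = np.minimum(frame["degree_sum"], degree_cap)

    z_scores = []
    group_rows = []
    skipped = 0
    for lo, hi in distance_bins:
        in_bin = frame[(frame["distance"] >= lo) & (frame["distance"] < hi)]
        for deg, group in in_bin.groupby("degree_group"):
            for low_s, high_s in (("0", "1"), ("1", "2+")):
                x_low = group.loc[group["stratum"] == low_s, "support"].to_numpy()
                x_high = group.loc[group["stratum"] == high_s, "support"].to_numpy()
                if len(x_low) < min_per_stratum or len(x_high) < min_per_stratum:
                    skipped += 1
                    continue
                res = sps.mannwhitneyu(x_high, x_low, alternative="greater")
                p_one = float(res.pvalue)
                z = float(sps.norm.isf(min(max(p_one, 1e-300), 1 - 1e-16)))
                z_scores.append(z)
                group_rows.append(
                    {
                        "bin_lo": lo,
                        "bin_hi": hi,
                        "degree_group": int(deg),
                        "comparison": f"{low_s}_vs_{high_s}",
                        "n_low": len(x_low),
                        "n_high": len(x_high),
                        "p_one_tailed": p_one,
                        "z": z,
                    }
                )
    if not z_scores:
        return {
            "groups": pd.DataFrame(group_rows),
            "n_groups": 0,
            "n_skipped": skipped,
            "combined_z": float("nan"),
            "combined_p": float("nan"),
        }
    combined_z, combined_p = stouffer(z_scores, two_tailed=True)
    return {
        "groups": pd.DataFrame(group_rows),
        "n_groups": len(z_scores),
        "n_skipped": skipped,
        "combined_z": combined_z,
        "combined_p": combined_p,
    }
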