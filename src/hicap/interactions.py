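"""Aggregation of filtered read pairs into interaction calls.

Interaction types: PD (promoter-distal), PP (promoter-promoter) and DD
(distal-distal). A call requires the per-replicate read support to reach
``min_support`` in every replicate.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping

import numpy as np
import pandas as pd

from .fragmap import FragmentMap, ProbeTargetSet, parse_fragment_id

__all__ = [
    "count_support",
    "call_interactions",
    "call_dd",
    "annotate_closest_gene",
    "gene_level_calls",
    "fragment_density_diagnostic",
]


def count_support(
    pairs_by_replicate: Mapping[str, pd.DataFrame],
    targets: ProbeTargetSet,
) -> pd.DataFrame:
    """Accumulate per-replicate read support for candidate interactions.

    Input pairs must have passed :func:`hicap.pairs.on_target_filter` (they
    carry promoters1/promoters2 annotations and frag1/frag2 ids). Pairs with
    both ends on promoter targets contribute to PP counts under a canonical
    (sorted) promoter-pair key and never to PD counts; single-anchored pairs
    contribute PD counts keyed on (promoter, partner fragment).

    Returns a long DataFrame: type, anchor, partner, one ``support_<rep>``
    column per replicate.
    """
    replicates = list(pairs_by_replicate)
    counts: dict[tuple[str, str, str], np.ndarray] = defaultdict(
        lambda: np.zeros(len(replicates), dtype=np.int64)
    )
    for ri, rep in enumerate(replicates):
        pairs = pairs_by_replicate[rep]
        for row in pairs.itertuples(index=False):
            p1, p2 = row.promoters1, row.promoters2
            if p1 and p2:
                for a in p1:
                    for b in p2:
                        if a == b:
                            continue
                        key = ("PP",) + tuple(sorted((a, b)))
                        counts[key][ri] += 1
            elif p1:
                for a in p1:
                    counts[("PD", a, row.frag2)][ri] += 1
            elif p2:
                for b in p2:
                    counts[("PD", b, row.frag1)][ri] += 1
    rows = [key + tuple(v) for key, v in counts.items()]
    cols = ["type", "anchor", "partner"] + [f"support_{r}" for r in replicates]
    return pd.DataFrame(rows, columns=cols)


def _support_columns(counts: pd.DataFrame) -> list[str]:
    return [c for c in counts.columns if c.startswith("support_")]


def call_interactions(
    counts: pd.DataFrame,
    targets: ProbeTargetSet,
    min_support: int = 3,
) -> pd.DataFrame:
    """Call interactions supported by >= min_support reads in every replicate.

    Adds coordinates for both sides and the anchor-midpoint to
    partner-midpoint distance (NaN and trans=True for trans-chromosomal
    calls). Promoter anchors use the midpoint of the promoter's probe-target
    span; PP partners likewise.
    """
    sup_cols = _support_columns(counts)
    if not sup_cols:
        raise ValueError("counts table has no support columns")
    called = counts[(counts[sup_cols] >= min_support).all(axis=1)].reset_index(drop=True)
    span = targets.promoter_span().set_index("promoter_id")

    rows = []
    for row in called.itertuples(index=False):
        sup = [getattr(row, c) for c in sup_cols]
        if row.type == "PP":
            a = span.loc[row.anchor]
            b = span.loc[row.partner]
            a_chrom, a_start, a_end = a["chrom"], int(a["start"]), int(a["end"])
            b_chrom, b_start, b_end = b["chrom"], int(b["start"]), int(b["end"])
            gene = a["gene_id"]
        else:
            a = span.loc[row.anchor]
            a_chrom, a_start, a_end = a["chrom"], int(a["start"]), int(a["end"])
            b_chrom, b_start, b_end = parse_fragment_id(row.partner)
            gene = a["gene_id"]
        trans = a_chrom != b_chrom
        mid_a = (a_start + a_end) // 2
        mid_b = (b_start + b_end) // 2
        distance = np.nan if trans else float(abs(mid_b - mid_a))
        rows.append(
            (
                row.type,
                row.anchor,
                row.partner,
                gene,
                a_chrom,
                a_start,
                a_end,
                b_chrom,
                b_start,
                b_end,
                trans,
                distance,
                *sup,
            )
        )
    cols = [
        "type",
        "anchor",
        "partner",
        "gene_id",
        "anchor_chrom",
        "anchor_start",
        "anchor_end",
        "partner_chrom",
        "partner_start",
        "partner_end",
        "trans",
        "distance",
        *sup_cols,
    ]
    calls = pd.DataFrame(rows, columns=cols)
    return calls.sort_values(["type", "anchor", "partner"]).reset_index(drop=True)


def call_dd(
    pairs_by_replicate: Mapping[str, pd.DataFrame],
    called_pd: pd.DataFrame,
    min_support: int = 3,
) -> pd.DataFrame:
    """Distal-distal calls restricted to distal fragments of called PD
    interactions.

    `pairs_by_replicate` here are the deduplicated *valid* pairs (before the
    on-target filter) with fragment annotations; both ends must fall in
    distinct fragments that appear as PD partners, and neither end may sit on
    a promoter target (pairs carrying promoter annotations are skipped when
    present).
    """
    distal = set(called_pd.loc[called_pd["type"] == "PD", "partner"])
    replicates = list(pairs_by_replicate)
    counts: dict[tuple[str, str], np.ndarray] = defaultdict(
        lambda: np.zeros(len(replicates), dtype=np.int64)
    )
    if distal:
        for ri, rep in enumerate(replicates):
            pairs = pairs_by_replicate[rep]
            has_promoters = "promoters1" in pairs.columns
            for row in pairs.itertuples(index=False):
                if has_promoters and (row.promoters1 or row.promoters2):
                    continue
                f1, f2 = row.frag1, row.frag2
                if f1 == f2 or f1 not in distal or f2 not in distal:
                    continue
                counts[tuple(sorted((f1, f2)))][ri] += 1
    rows = []
    for (f1, f2), sup in counts.items():
        if (sup >= min_support).all():
            c1, s1, e1 = parse_fragment_id(f1)
            c2, s2, e2 = parse_fragment_id(f2)
            trans = c1 != c2
            distance = (
                np.nan if trans else float(abs((s2 + e2) // 2 - (s1 + e1) // 2))
            )
            rows.append(
                ("DD", f1, f2, "", c1, s1, e1, c2, s2, e2, trans, distance, *sup)
            )
    cols = [
        "type",
        "anchor",
        "partner",
        "gene_id",
        "anchor_chrom",
        "anchor_start",
        "anchor_end",
        "partner_chrom",
        "partner_start",
        "partner_end",
        "trans",
        "distance",
        *[f"support_{r}" for r in replicates],
    ]
    return pd.DataFrame(rows, columns=cols).sort_values(["anchor", "partner"]).reset_index(drop=True)


def closest_tss(
    tss_table: pd.DataFrame, chrom: str, pos: int
) -> tuple[str, str] | None:
    """(gene_id, promoter_id) of the TSS nearest `pos`; lower-coordinate TSS
    wins exact ties."""
    sub = tss_table[tss_table["chrom"] == chrom]
    if sub.empty:
        return None
    sub = sub.sort_values(["pos", "promoter_id"], kind="stable")
    positions = sub["pos"].to_numpy()
    dist = np.abs(positions - pos)
    i = int(np.argmin(dist))  # argmin takes the first (lowest-coordinate) tie
    row = sub.iloc[i]
    return str(row["gene_id"]), str(row["promoter_id"])


def annotate_closest_gene(calls: pd.DataFrame, tss_table: pd.DataFrame) -> pd.DataFrame:
    """Flag PD calls whose distal fragment's nearest TSS belongs to the
    interacting gene. Trans calls are flagged but not annotated."""
    calls = calls.copy()
    closest_genes: list[str | None] = []
    flags: list[object] = []
    for row in calls.itertuples(index=False):
        if row.type != "PD" or row.trans:
            closest_genes.append(None)
            flags.append(pd.NA)
            continue
        mid = (int(row.partner_start) + int(row.partner_end)) // 2
        hit = closest_tss(tss_table, row.partner_chrom, mid)
        if hit is None:
            closest_genes.append(None)
            flags.append(pd.NA)
        else:
            closest_genes.append(hit[0])
            flags.append(hit[0] == row.gene_id)
    calls["closest_gene"] = closest_genes
    calls["closest_gene_flag"] = flags
    return calls


def gene_level_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Reporting view: roll promoter-level calls up to unique genes."""
    pd_calls = calls[calls["type"] == "PD"]
    return (
        pd_calls.groupby("gene_id")
        .agg(n_interactions=("partner", "nunique"))
        .reset_index()
    )


def fragment_density_diagnostic(
    calls: pd.DataFrame, tss_table: pd.DataFrame, fragmap: FragmentMap, window: int = 10000
) -> float:
    """Squared Pearson correlation between the number of restriction
    fragments within `window` of each TSS and the number of interactions
    anchored on that promoter. Diagnostic only."""
    per_anchor = calls[calls["type"] == "PD"].groupby("anchor").size()
    n_frags = []
    n_calls = []
    for row in tss_table.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in fragmap.boundaries:
            continue
        b = fragmap.boundaries[chrom]
        lo = max(0, int(row.pos) - window)
        hi = min(int(b[-1]), int(row.pos) + window)
        n_frags.append(int(np.searchsorted(b, hi) - np.searchsorted(b, lo)))
        n_calls.append(int(per_anchor.get(row.promoter_id, 0)))
    if len(n_frags) < 3 or np.std(n_frags) == 0 or np.std(n_calls) == 0:
        return float("nan")
    r = np.corrcoef(n_frags, n_calls)[0, 1]
    return float(r**2)
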