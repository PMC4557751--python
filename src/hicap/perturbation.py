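"""TF-perturbation validation: do interaction-supported genes predict
upregulation after TF over-expression better than closest genes?"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fragmap import FragmentMap
from .interactions import closest_tss
from .stats import chi2_gof

__all__ = [
    "PerturbationCounts",
    "de_genes",
    "closest_genes",
    "connected_genes",
    "fold_improvement",
    "compound_test",
    "closest_split_test",
    "perturbation_counts",
]


@dataclass
class PerturbationCounts:
    """Counts for one TF: closest genes (Nc), interaction-supported
    non-closest genes (Nh), and their upregulated subsets (Uc, Uh)."""

    tf_name: str
    n_closest: int
    n_connected: int
    u_closest: int
    u_connected: int

    def __post_init__(self) -> None:
        if not (0 <= self.u_closest <= self.n_closest):
            raise ValueError("u_closest out of range")
        if not (0 <= self.u_connected <= self.n_connected):
            raise ValueError("u_connected out of range")


def de_genes(de_table: pd.DataFrame, fdr_max: float = 0.05, fc_min: float = 1.5) -> set[str]:
    """Genes with fdr <= fdr_max and fold_change strictly > fc_min."""
    mask = (de_table["fdr"] <= fdr_max) & (de_table["fold_change"] > fc_min)
    return set(de_table.loc[mask, "gene_id"])


def closest_genes(
    tfbs: pd.DataFrame, tss_table: pd.DataFrame
) -> tuple[set[str], pd.DataFrame]:
    """Per peak, the gene whose TSS is nearest the peak midpoint.

    Returns (unique gene set, per-peak assignment with an `assigned` flag;
    peaks on chromosomes without any TSS stay unassigned).
    """
    rows = []
    for row in tfbs.itertuples(index=False):
        mid = (int(row.start) + int(row.end)) // 2
        hit = closest_tss(tss_table, str(row.chrom), mid)
        rows.append(
            (row.chrom, row.start, row.end, mid, hit[0] if hit else None, hit is not None)
        )
    assign = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "midpoint", "gene_id", "assigned"]
    )
    return set(assign.loc[assign["assigned"], "gene_id"]), assign


def connected_genes(
    tfbs: pd.DataFrame,
    calls: pd.DataFrame,
    fragmap: FragmentMap,
    min_distance: int = 0,
    exclude_pp: bool = True,
) -> set[str]:
    """Genes whose promoter interacts with the restriction fragment
    containing a peak midpoint.

    `min_distance` drops interactions shorter than the given span (the 15-kb
    variant); PP interactions are excluded by default.
    """
    sub = calls[calls["type"] == "PD"] if exclude_pp else calls
    if min_distance > 0:
        sub = sub[(sub["trans"]) | (sub["distance"] >= min_distance)]
    by_fragment: dict[str, set[str]] = {}
    for row in sub.itertuples(index=False):
        by_fragment.setdefault(row.partner, set()).add(row.gene_id)
    genes: set[str] = set()
    for row in tfbs.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in fragmap.boundaries:
            continue
        mid = (int(row.start) + int(row.end)) // 2
        if mid >= fragmap.chrom_length(chrom):
            continue
        c, s, e = fragmap.locate(chrom, mid)
        frag = f"{c}:{s}-{e}"
        genes |= by_fragment.get(frag, set())
    return genes


def perturbation_counts(
    tf_name: str,
    tfbs: pd.DataFrame,
    calls: pd.DataFrame,
    fragmap: FragmentMap,
    de_set: set[str],
    tss_table: pd.DataFrame,
    min_distance: int = 0,
) -> PerturbationCounts:
    """Assemble Nc/Nh/Uc/Uh for one TF.

    Nh counts interaction-supported genes that are *not* closest genes (the
    non-closest comparison of the functional test); Nc counts all closest
    genes irrespective of support.
    """
    closest, _ = closest_genes(tfbs, tss_table)
    connected = connected_genes(tfbs, calls, fragmap, min_distance=min_distance)
    non_closest = connected - closest
    return PerturbationCounts(
        tf_name=tf_name,
        n_closest=len(closest),
        n_connected=len(non_closest),
        u_closest=len(closest & de_set),
        u_connected=len(non_closest & de_set),
    )


def fold_improvement(counts: PerturbationCounts) -> dict:
    """Fold = (Uh/Nh)/(Uc/Nc); chi-square with (Uh, Uc) observed and the
    Nh:Nc split as expected proportions over Uh+Uc events."""
    nc, nh = counts.n_closest, counts.n_connected
    uc, uh = counts.u_closest, counts.u_connected
    if nc <= 0 or nh <= 0:
        raise ValueError("Nc and Nh must be positive")
    if uc + uh == 0:
        raise ValueError("no upregulated genes in either set")
    total = uc + uh
    expected = [total * nh / (nh + nc), total * nc / (nh + nc)]
    chi2, p = chi2_gof([uh, uc], expected)
    if uc == 0:
        return {"fold": float("inf"), "fold_defined": False, "chi2": chi2, "chi2_p": p}
    fold = (uh / nh) / (uc / nc)
    return {"fold": fold, "fold_defined": True, "chi2": chi2, "chi2_p": p}


def compound_test(per_tf: list[PerturbationCounts]) -> dict:
    """Element-wise sums over TFs, then the same fold/chi-square test."""
    if not per_tf:
        raise ValueError("need at least one TF")
    summed = PerturbationCounts(
        tf_name="compound",
        n_closest=sum(c.n_closest for c in per_tf),
        n_connected=sum(c.n_connected for c in per_tf),
        u_closest=sum(c.u_closest for c in per_tf),
        u_connected=sum(c.u_connected for c in per_tf),
    )
    return fold_improvement(summed)


def closest_split_test(
    tfbs: pd.DataFrame,
    calls: pd.DataFrame,
    fragmap: FragmentMap,
    de_set: set[str],
    tss_table: pd.DataFrame,
    min_distance: int = 0,
) -> dict:
    """Split closest genes into with / without interaction support and
    compare upregulation rates (Fisher's exact test on the 2x2 table)."""
    closest, _ = closest_genes(tfbs, tss_table)
    connected = connected_genes(tfbs, calls, fragmap, min_distance=min_distance)
    with_support = closest & connected
    without_support = closest - connected
    if not with_support or not without_support:
        raise ValueError("degenerate partition of closest genes")
    a = len(with_support & de_set)
    b = len(with_support) - a
    c = len(without_support & de_set)
    d = len(without_support) - c
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    rate_with = a / len(with_support)
    rate_without = c / len(without_support)
    fold = np.inf if rate_without == 0 else rate_with / rate_without
    return {
        "n_with_support": len(with_support),
        "n_without_support": len(without_support),
        "u_with_support": a,
        "u_without_support": c,
        "fold": float(fold),
        "odds_ratio": float(odds),
        "fisher_p": float(p),
    }
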