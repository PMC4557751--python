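"""Pairing, classification and filtering of independently mapped read ends.

All tables are pandas DataFrames. Aligned ends carry columns
``read_id, chrom, pos, strand``; paired tables carry the two ends in
canonical order (sorted by chrom, pos, strand) so pair identity is
orientation-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragmap import FragmentMap, ProbeTargetSet, fragment_id
from .intervals import GenomicIntervals

__all__ = [
    "pair_ends",
    "dedupe",
    "classify",
    "on_target_filter",
    "capture_stats",
    "FilterReport",
    "filter_pairs",
]

END_COLUMNS = ["read_id", "chrom", "pos", "strand"]
PAIR_COLUMNS = [
    "read_id",
    "chrom1",
    "pos1",
    "strand1",
    "chrom2",
    "pos2",
    "strand2",
]


@dataclass
class FilterReport:
    """Per-class pair accounting for one replicate."""

    n_input_ends: int = 0
    n_singletons: int = 0
    n_pairs: int = 0
    n_duplicate: int = 0
    n_same_fragment: int = 0
    n_too_close: int = 0
    n_off_target: int = 0
    n_retained: int = 0
    extra: dict = field(default_factory=dict)

    def conserved(self) -> bool:
        return (
            self.n_pairs
            == self.n_duplicate
            + self.n_same_fragment
            + self.n_too_close
            + self.n_off_target
            + self.n_retained
        )

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_input_ends",
            "n_singletons",
            "n_pairs",
            "n_duplicate",
            "n_same_fragment",
            "n_too_close",
            "n_off_target",
            "n_retained",
        )}
        d.update(self.extra)
        return d


def pair_ends(ends: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Join the two mapped ends of each read id into one canonical pair.

    Returns (pairs, n_singletons). Read ids seen once are dropped and
    counted; more than two ends per read id is an error.
    """
    ends = ends[END_COLUMNS]
    counts = ends["read_id"].value_counts()
    if (counts > 2).any():
        bad = counts.index[counts > 2][0]
        raise ValueError(f"read id {bad!r} occurs more than twice")
    n_singletons = int((counts == 1).sum())
    paired_ids = counts.index[counts == 2]
    sub = ends[ends["read_id"].isin(paired_ids)].copy()
    if sub.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS), n_singletons
    # canonical within-pair order: sort ends by (chrom, pos, strand)
    sub = sub.sort_values(["read_id", "chrom", "pos", "strand"], kind="stable")
    first = sub.groupby("read_id", sort=False).nth(0)
    second = sub.groupby("read_id", sort=False).nth(1)
    pairs = pd.DataFrame(
        {
            "read_id": first["read_id"].to_numpy(),
            "chrom1": first["chrom"].to_numpy(),
            "pos1": first["pos"].to_numpy(),
            "strand1": first["strand"].to_numpy(),
            "chrom2": second["chrom"].to_numpy(),
            "pos2": second["pos"].to_numpy(),
            "strand2": second["strand"].to_numpy(),
        }
    )
    return pairs.sort_values(["chrom1", "pos1", "chrom2", "pos2"]).reset_index(drop=True), n_singletons


def dedupe(pairs: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop pairs whose two ends share exact (chrom, pos, strand) with a
    previously seen pair; one representative is retained per signature.
    Deduplication is per call, i.e. per replicate."""
    key_cols = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    keep = ~pairs.duplicated(subset=key_cols, keep="first")
    return pairs[keep].reset_index(drop=True), int((~keep).sum())


def classify(
    pairs: pd.DataFrame, fragmap: FragmentMap, min_distance: int = 1000
) -> pd.DataFrame:
    """Assign fragments and a validity class to each pair.

    Classes: ``same_fragment`` (both ends in one fragment), ``too_close``
    (same chromosome, < min_distance apart — self-ligation removal),
    ``valid`` otherwise. Trans pairs are always valid. Adds columns
    frag1/frag2 (fragment ids), frag{1,2}_start/end, validity_class.
    """
    pairs = pairs.copy()
    n = len(pairs)
    f1s = np.zeros(n, dtype=np.int64)
    f1e = np.zeros(n, dtype=np.int64)
    f2s = np.zeros(n, dtype=np.int64)
    f2e = np.zeros(n, dtype=np.int64)
    for chrom in set(pairs["chrom1"]).union(pairs["chrom2"]):
        m1 = (pairs["chrom1"] == chrom).to_numpy()
        if m1.any():
            s, e = fragmap.locate_many(chrom, pairs.loc[m1, "pos1"].to_numpy())
            f1s[m1], f1e[m1] = s, e
        m2 = (pairs["chrom2"] == chrom).to_numpy()
        if m2.any():
            s, e = fragmap.locate_many(chrom, pairs.loc[m2, "pos2"].to_numpy())
            f2s[m2], f2e[m2] = s, e
    pairs["frag1_start"], pairs["frag1_end"] = f1s, f1e
    pairs["frag2_start"], pairs["frag2_end"] = f2s, f2e
    pairs["frag1"] = [
        fragment_id(c, s, e) for c, s, e in zip(pairs["chrom1"], f1s, f1e)
    ]
    pairs["frag2"] = [
        fragment_id(c, s, e) for c, s, e in zip(pairs["chrom2"], f2s, f2e)
    ]
    same_chrom = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
    same_frag = same_chrom & (f1s == f2s) & (f1e == f2e)
    close = (
        same_chrom
        & ~same_frag
        & (np.abs(pairs["pos1"].to_numpy() - pairs["pos2"].to_numpy()) < min_distance)
    )
    cls = np.where(same_frag, "same_fragment", np.where(close, "too_close", "valid"))
    pairs["validity_class"] = cls
    return pairs


def _target_index(targets: ProbeTargetSet) -> GenomicIntervals:
    return GenomicIntervals(targets.frame)


def _promoters_at(
    index: GenomicIntervals, targets: ProbeTargetSet, chrom: str, pos: int
) -> tuple[str, ...]:
    rows = index.query_point(chrom, pos)
    promoters: list[str] = []
    for r in rows:
        for pid in targets.frame.iloc[r]["promoter_ids"]:
            if pid not in promoters:
                promoters.append(pid)
    return tuple(sorted(promoters))


def on_target_filter(
    pairs: pd.DataFrame, targets: ProbeTargetSet
) -> tuple[pd.DataFrame, int]:
    """Retain pairs with >=1 end inside a probe target region.

    Adds columns promoters1/promoters2 (tuples of promoter ids covering each
    end; empty tuple when off-target). Pairs with both ends on promoter
    targets are promoter-promoter candidates. Returns (retained, n_dropped).
    """
    index = _target_index(targets)
    p1 = [
        _promoters_at(index, targets, c, int(p))
        for c, p in zip(pairs["chrom1"], pairs["pos1"])
    ]
    p2 = [
        _promoters_at(index, targets, c, int(p))
        for c, p in zip(pairs["chrom2"], pairs["pos2"])
    ]
    pairs = pairs.copy()
    pairs["promoters1"] = p1
    pairs["promoters2"] = p2
    on = np.array([bool(a) or bool(b) for a, b in zip(p1, p2)])
    return pairs[on].reset_index(drop=True), int((~on).sum())


def capture_stats(
    ends: pd.DataFrame, targets: ProbeTargetSet, genome_size: int
) -> dict:
    """On-target fraction of aligned ends and fold enrichment over the
    genomic share of the target space.

    fold_enrichment = on_target_fraction / (target bp / genome bp).
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if len(targets) == 0:
        raise ValueError("empty target set")
    if len(ends) == 0:
        raise ValueError("no aligned ends")
    index = _target_index(targets)
    n_on = sum(
        1
        for c, p in zip(ends["chrom"], ends["pos"])
        if len(index.query_point(str(c), int(p))) > 0
    )
    fraction = n_on / len(ends)
    target_share = targets.total_bp() / genome_size
    return {
        "n_ends": int(len(ends)),
        "n_on_target": int(n_on),
        "on_target_fraction": fraction,
        "target_genome_fraction": target_share,
        "fold_enrichment": fraction / target_share,
    }


def filter_pairs(
    ends: pd.DataFrame,
    fragmap: FragmentMap,
    targets: ProbeTargetSet,
    min_distance: int = 1000,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full per-replicate filter chain: pair -> dedupe -> classify -> on-target.

    Returns the retained annotated pairs and a conservation report.
    """
    report = FilterReport(n_input_ends=len(ends))
    paired, report.n_singletons = pair_ends(ends)
    report.n_pairs = len(paired)
    deduped, report.n_duplicate = dedupe(paired)
    classified = classify(deduped, fragmap, min_distance=min_distance)
    report.n_same_fragment = int((classified["validity_class"] == "same_fragment").sum())
    report.n_too_close = int((classified["validity_class"] == "too_close").sum())
    valid = classified[classified["validity_class"] == "valid"].reset_index(drop=True)
    retained, report.n_off_target = on_target_filter(valid, targets)
    report.n_retained = len(retained)
    return retained, report
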