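"""Lightweight genomic interval index.

A per-chromosome sorted-start index with a running maximum of interval ends,
supporting point and interval stabbing queries in O(log n + k). Intervals may
overlap; coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["GenomicIntervals"]


class GenomicIntervals:
    """Index a table of (chrom, start, end) rows for overlap queries.

    Parameters
    ----------
    frame:
        DataFrame with at least ``chrom``, ``start`` and ``end`` columns.
        Row positions (0..n-1) are the handles returned by queries.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            order = np.argsort(sub["start"].to_numpy(), kind="stable")
            starts = sub["start"].to_numpy()[order]
            ends = sub["end"].to_numpy()[order]
            rows = sub.index.to_numpy()[order]
            cummax = np.maximum.accumulate(ends)
            self._by_chrom[str(chrom)] = (starts, ends, rows, cummax)

    def __len__(self) -> int:
        return len(self.frame)

    def query(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row indices of all intervals overlapping [start, end) by >=1 bp."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return np.empty(0, dtype=int)
        starts, ends, rows, cummax = entry
        hi = int(np.searchsorted(starts, end, side="left"))
        # leftmost candidate whose running-max end can still reach past `start`
        lo = int(np.searchsorted(cummax[:hi], start, side="right"))
        if lo >= hi:
            return np.empty(0, dtype=int)
        mask = ends[lo:hi] > start
        return rows[lo:hi][mask]

    def query_point(self, chrom: str, pos: int) -> np.ndarray:
        return self.query(chrom, pos, pos + 1)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return len(self.query(chrom, start, end)) > 0

    def overlap_flags(self, regions: pd.DataFrame) -> np.ndarray:
        """Boolean per row of `regions`: overlaps any indexed interval."""
        flags = np.zeros(len(regions), dtype=bool)
        for i, (chrom, start, end) in enumerate(
            zip(regions["chrom"], regions["start"], regions["end"])
        ):
            flags[i] = self.overlaps(str(chrom), int(start), int(end))
        return flags

    def covering_points(self, chroms: Iterable[str], positions: Iterable[int]) -> list[np.ndarray]:
        return [self.query_point(str(c), int(p)) for c, p in zip(chroms, positions)]
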