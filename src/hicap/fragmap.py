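"""In-silico restriction digestion and promoter probe-target design.

Coordinates are 0-based half-open. A cut is placed at the first base of every
occurrence of the recognition sequence, so for MboI (^GATC) the site stays on
the downstream fragment. Fragments tile each chromosome exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FragmentMap",
    "ProbeTargetSet",
    "digest",
    "mean_fragment_length",
    "design_probe_targets",
    "locate_fragment",
]


def fragment_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def parse_fragment_id(frag_id: str) -> tuple[str, int, int]:
    chrom, span = frag_id.rsplit(":", 1)
    start, end = span.split("-")
    return chrom, int(start), int(end)


@dataclass
class FragmentMap:
    """Ordered restriction fragments per chromosome.

    ``boundaries[chrom]`` is the sorted array of fragment boundaries,
    including 0 and the chromosome length; fragment i spans
    [boundaries[i], boundaries[i+1]).
    """

    boundaries: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.boundaries)

    def chrom_length(self, chrom: str) -> int:
        return int(self.boundaries[chrom][-1])

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.boundaries[chrom]) - 1
        return sum(len(b) - 1 for b in self.boundaries.values())

    def fragments(self, chrom: str) -> Iterator[tuple[int, int]]:
        b = self.boundaries[chrom]
        for i in range(len(b) - 1):
            yield int(b[i]), int(b[i + 1])

    def lengths(self) -> np.ndarray:
        """All fragment lengths, concatenated over chromosomes."""
        parts = [np.diff(b) for b in self.boundaries.values()]
        return np.concatenate(parts) if parts else np.empty(0, dtype=int)

    def locate(self, chrom: str, pos: int) -> tuple[str, int, int]:
        """Fragment (chrom, start, end) containing `pos` (half-open)."""
        b = self.boundaries[chrom]
        if pos < 0 or pos >= b[-1]:
            raise ValueError(f"position {pos} outside chromosome {chrom} [0,{b[-1]})")
        i = int(np.searchsorted(b, pos, side="right")) - 1
        return chrom, int(b[i]), int(b[i + 1])

    def locate_many(self, chrom: str, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized locate: (starts, ends) arrays for `positions`."""
        b = self.boundaries[chrom]
        pos = np.asarray(positions)
        if pos.size and (pos.min() < 0 or pos.max() >= b[-1]):
            raise ValueError(f"positions outside chromosome {chrom}")
        idx = np.searchsorted(b, pos, side="right") - 1
        return b[idx], b[idx + 1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chroms:
            for start, end in self.fragments(chrom):
                rows.append((chrom, start, end, fragment_id(chrom, start, end)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "fragment_id"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FragmentMap":
        boundaries = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not np.array_equal(starts[1:], ends[:-1]):
                raise ValueError(f"fragments on {chrom} do not tile contiguously")
            boundaries[str(chrom)] = np.concatenate([starts, ends[-1:]]).astype(np.int64)
        return cls(boundaries)


def digest(genome: Mapping[str, str], site: str = "GATC") -> FragmentMap:
    """Digest `genome` at every occurrence of `site`.

    Cut positions are the 0-based starts of all (possibly overlapping)
    occurrences; zero-length fragments from a cut at position 0 are
    suppressed. N runs never match.
    """
    if not genome:
        raise ValueError("empty genome")
    site = site.upper()
    if not site or set(site) - set("ACGT"):
        raise ValueError(f"invalid recognition sequence: {site!r}")
    boundaries = {}
    for chrom, seq in genome.items():
        length = len(seq)
        if length == 0:
            raise ValueError(f"chromosome {chrom} has zero length")
        seq = seq.upper()
        cuts = [0]
        i = seq.find(site)
        while i != -1:
            cuts.append(i)
            i = seq.find(site, i + 1)  # overlapping occurrences all cut
        cuts.append(length)
        boundaries[chrom] = np.unique(np.asarray(cuts, dtype=np.int64))
    return FragmentMap(boundaries)


def mean_fragment_length(fragmap: FragmentMap) -> float:
    """Arithmetic mean fragment length over all chromosomes."""
    lengths = fragmap.lengths()
    if lengths.size == 0:
        raise ValueError("empty fragment map")
    return float(lengths.mean())


def locate_fragment(fragmap: FragmentMap, chrom: str, pos: int) -> tuple[str, int, int]:
    """The unique fragment with start <= pos < end."""
    return fragmap.locate(chrom, pos)


@dataclass
class ProbeTargetSet:
    """Capture-probe target regions around promoter TSSs.

    ``frame`` has one row per unique region with columns chrom, start, end,
    promoter_ids (tuple), gene_ids (tuple), is_control (bool),
    clipped (bool: one side hit a chromosome end rather than a cut site).
    """

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    def total_bp(self) -> int:
        return int((self.frame["end"] - self.frame["start"]).sum())

    def promoter_span(self) -> pd.DataFrame:
        """Per promoter: chrom, span start/end over its targets, midpoint, gene."""
        rows = []
        for row in self.frame.itertuples(index=False):
            for pid, gid in zip(row.promoter_ids, row.gene_ids):
                rows.append((pid, gid, row.chrom, row.start, row.end))
        df = pd.DataFrame(rows, columns=["promoter_id", "gene_id", "chrom", "start", "end"])
        span = df.groupby("promoter_id").agg(
            gene_id=("gene_id", "first"),
            chrom=("chrom", "first"),
            start=("start", "min"),
            end=("end", "max"),
        )
        span["midpoint"] = (span["start"] + span["end"]) // 2
        return span.reset_index()

    def to_bed_frame(self) -> pd.DataFrame:
        names = [
            ";".join(f"{p}|{g}" for p, g in zip(r.promoter_ids, r.gene_ids))
            for r in self.frame.itertuples(index=False)
        ]
        return pd.DataFrame(
            {
                "chrom": self.frame["chrom"],
                "start": self.frame["start"],
                "end": self.frame["end"],
                "name": names,
                "score": np.where(self.frame["is_control"], 1, 0),
                "strand": ".",
            }
        )

    @classmethod
    def from_bed_frame(cls, bed: pd.DataFrame) -> "ProbeTargetSet":
        rows = []
        for r in bed.itertuples(index=False):
            pairs = [tuple(x.split("|", 1)) for x in str(r.name).split(";")]
            rows.append(
                (
                    r.chrom,
                    int(r.start),
                    int(r.end),
                    tuple(p for p, _ in pairs),
                    tuple(g for _, g in pairs),
                    bool(int(getattr(r, "score", 0))),
                    False,
                )
            )
        return cls(
            pd.DataFrame(
                rows,
                columns=["chrom", "start", "end", "promoter_ids", "gene_ids", "is_control", "clipped"],
            )
        )


def design_probe_targets(
    tss_table: pd.DataFrame,
    fragmap: FragmentMap,
    flank: int = 150,
    merge_below: int = 300,
) -> ProbeTargetSet:
    """Design capture targets flanking the restriction sites around each TSS.

    For each TSS, the closest cut site upstream and downstream is found (the
    boundaries of the fragment containing the TSS). If the two cuts are less
    than `merge_below` apart, a single target spans the whole inter-cut
    region; otherwise two targets of length `flank` abut the cuts on the
    TSS-facing side. Identical regions arising from different promoters are
    emitted once with all promoter ids attached.

    `tss_table` needs columns chrom, pos, promoter_id, gene_id; an optional
    boolean is_control column marks negative-control entries.
    """
    regions: dict[tuple[str, int, int], dict] = {}
    has_control = "is_control" in tss_table.columns
    for row in tss_table.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in fragmap.boundaries:
            raise ValueError(f"TSS chromosome {chrom} absent from fragment map")
        _, up, down = fragmap.locate(chrom, int(row.pos))
        chrom_len = fragmap.chrom_length(chrom)
        clipped = up == 0 or down == chrom_len
        if down - up < merge_below:
            spans = [(up, down)]
        else:
            spans = [(up, min(up + flank, down)), (max(down - flank, up), down)]
        is_control = bool(getattr(row, "is_control", False)) if has_control else False
        for start, end in spans:
            key = (chrom, start, end)
            entry = regions.setdefault(
                key, {"promoters": [], "genes": [], "is_control": is_control, "clipped": clipped}
            )
            if row.promoter_id not in entry["promoters"]:
                entry["promoters"].append(row.promoter_id)
                entry["genes"].append(row.gene_id)
            entry["clipped"] = entry["clipped"] or clipped
    rows = [
        (
            chrom,
            start,
            end,
            tuple(e["promoters"]),
            tuple(e["genes"]),
            e["is_control"],
            e["clipped"],
        )
        for (chrom, start, end), e in sorted(regions.items())
    ]
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "promoter_ids", "gene_ids", "is_control", "clipped"]
    )
    return ProbeTargetSet(frame)
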