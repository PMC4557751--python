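"""Readers and writers for the formats the pipeline consumes and emits:
FASTA genomes, BED tracks, tabular aligned ends (TSV or SAM), TSV tables and
GFF interaction export."""

from __future__ import annotations

from pathlib import Path
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fragmap import FragmentMap, ProbeTargetSet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_ends",
    "write_ends",
    "read_tsv",
    "write_tsv",
    "write_fragments_bed",
    "read_fragments_bed",
    "write_probes_bed",
    "read_probes_bed",
    "write_interactions_gff",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    genome = {str(rec.id): str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise ValueError(f"no sequences in {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in frame.columns]
    frame[cols].to_csv(str(path), sep="\t", header=False, index=False)


def read_ends(path: str | Path) -> pd.DataFrame:
    """Aligned ends from a 4-column TSV (read_id, chrom, pos, strand) or a
    SAM file of independently mapped single-end records."""
    path = Path(path)
    if path.suffix.lower() in {".sam", ".bam"}:
        import pysam  # optional heavy dependency, only for SAM/BAM input

        rows = []
        with pysam.AlignmentFile(str(path), check_sq=False) as handle:
            for rec in handle:
                if rec.is_unmapped:
                    continue
                rows.append(
                    (
                        rec.query_name,
                        rec.reference_name,
                        int(rec.reference_start),
                        "-" if rec.is_reverse else "+",
                    )
                )
        return pd.DataFrame(rows, columns=["read_id", "chrom", "pos", "strand"])
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df.columns = ["read_id", "chrom", "pos", "strand"][: df.shape[1]]
    return df


def write_ends(ends: pd.DataFrame, path: str | Path) -> None:
    ends[["read_id", "chrom", "pos", "strand"]].to_csv(
        str(path), sep="\t", header=False, index=False
    )


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(str(path), sep="\t", index=False)


def write_fragments_bed(fragmap: FragmentMap, path: str | Path) -> None:
    frame = fragmap.to_frame().rename(columns={"fragment_id": "name"})
    write_bed(frame, path)


def read_fragments_bed(path: str | Path) -> FragmentMap:
    frame = read_bed(path)
    return FragmentMap.from_frame(frame.rename(columns={"name": "fragment_id"}))


def write_probes_bed(targets: ProbeTargetSet, path: str | Path) -> None:
    write_bed(targets.to_bed_frame(), path)


def read_probes_bed(path: str | Path) -> ProbeTargetSet:
    return ProbeTargetSet.from_bed_frame(read_bed(path))


def write_interactions_gff(calls: pd.DataFrame, path: str | Path, source: str = "hicap") -> None:
    """Browser-style GFF: one feature per interaction side sharing a group
    id, so paired anchors stay linked in the display."""
    with open(path, "w") as out:
        for i, row in enumerate(calls.itertuples(index=False)):
            group = f"interaction_{i}; type {row.type}"
            for chrom, start, end, role in (
                (row.anchor_chrom, row.anchor_start, row.anchor_end, "anchor"),
                (row.partner_chrom, row.partner_start, row.partner_end, "partner"),
            ):
                out.write(
                    "\t".join(
                        [
                            str(chrom),
                            source,
                            role,
                            str(int(start) + 1),  # GFF is 1-based inclusive
                            str(int(end)),
                            ".",
                            ".",
                            ".",
                            group,
                        ]
                    )
                    + "\n"
                )


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    write_tsv(calls, path)


def read_calls(path: str | Path) -> pd.DataFrame:
    calls = read_tsv(path)
    if "trans" in calls.columns:
        calls["trans"] = calls["trans"].astype(bool)
    return calls
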