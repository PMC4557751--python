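"""Synthetic genomes, capture-Hi-C read pairs and omics tracks with planted
ground truth, so every pipeline stage is testable without external data.

Read ends are emitted as already-aligned positions; background contacts
follow a truncated power-law distance decay, planted loops receive boosted
Poisson pair counts, and duplicates are injected at a configurable rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fragmap as fm
from .fragmap import FragmentMap, ProbeTargetSet, fragment_id
from .intervals import GenomicIntervals

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimData",
    "simulate_genome",
    "simulate_reads",
    "simulate_omics",
    "simulate_all",
    "calls_from_truth",
]


@dataclass
class SimConfig:
    """Knobs for the synthetic dataset. All randomness flows from `seed`."""

    seed: int
    genome_length: int = 10_000_000
    n_chromosomes: int = 2
    gc: float = 0.5
    n_promoters: int = 200
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    # planted signal
    n_planted_loops: int = 300
    loop_rate: float = 8.0  # expected pairs per replicate per loop
    loop_distance_logmu: float = math.log(30_000)
    loop_distance_sigma: float = 0.8
    loop_distance_min: int = 5_000
    loop_distance_max: int = 500_000
    shared_enhancer_fraction: float = 0.2  # loops reusing an earlier distal fragment
    n_planted_pp: int = 40
    pp_rate: float = 6.0
    n_planted_ee: int = 40
    ee_rate: float = 6.0
    # background contacts
    pairs_per_replicate: int = 200_000
    decay_alpha: float = 1.0
    decay_min: int = 200
    decay_max: int = 2_000_000
    capture_bias: float = 0.01  # extra probability of a background end on a probe
    trans_fraction: float = 0.02
    duplicate_rate: float = 0.05
    n_replicates: int = 2
    # omics
    enhancer_mark_fraction: float = 0.8
    n_decoy_marks: int = 300
    tad_length_range: tuple[int, int] = (150_000, 400_000)
    tad_gap_range: tuple[int, int] = (0, 20_000)
    erna_signal: float = 5.0  # mean reads per kb at planted enhancers
    erna_noise: float = 0.2  # mean reads per kb elsewhere
    expression_correlation: float = 0.7
    n_tfs: int = 3
    tf_bind_fraction: float = 0.4
    n_decoy_peaks: int = 100
    baseline_up_rate: float = 0.05
    up_effect_size: float = 6.0  # 1.0 = null
    n_go_terms: int = 20
    go_shared_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("gc", "capture_bias", "trans_fraction", "duplicate_rate",
                     "enhancer_mark_fraction", "tf_bind_fraction", "baseline_up_rate",
                     "go_shared_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.pairs_per_replicate < 0 or self.n_replicates < 1:
            raise ValueError("invalid depth configuration")


@dataclass
class GroundTruth:
    """What was planted: loops, PP/EE contacts, enhancers, TADs, TF targets."""

    loops: pd.DataFrame
    pp_contacts: pd.DataFrame
    ee_contacts: pd.DataFrame
    enhancer_marks: pd.DataFrame | None = None
    tads: pd.DataFrame | None = None
    tf_targets: dict[str, set[str]] = field(default_factory=dict)
    upregulated: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class SimData:
    """Bundle of every generated input plus the ground truth."""

    config: SimConfig
    genome: dict[str, str]
    chrom_lengths: dict[str, int]
    tss_table: pd.DataFrame
    gene_annotation: pd.DataFrame
    fragmap: FragmentMap
    targets: ProbeTargetSet
    ends_by_replicate: dict[str, pd.DataFrame]
    truth: GroundTruth
    enhancer_marks: pd.DataFrame | None = None
    tads: pd.DataFrame | None = None
    gro_reads: pd.DataFrame | None = None
    gene_rpkm: pd.DataFrame | None = None
    distal_rpkm: pd.DataFrame | None = None
    tfbs: dict[str, pd.DataFrame] = field(default_factory=dict)
    de_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    go_table: pd.DataFrame | None = None


BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_genome(cfg: SimConfig) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Random genome with GC-controlled GATC density, TSS table and gene
    bodies. Promoters are placed one per evenly sized slot (minimum spacing
    by construction); an over-dense request fails."""
    rng = np.random.default_rng(cfg.seed)
    at = (1.0 - cfg.gc) / 2.0
    gcp = cfg.gc / 2.0
    probs = [at, gcp, gcp, at]
    chrom_len = cfg.genome_length // cfg.n_chromosomes
    genome: dict[str, str] = {}
    tss_rows = []
    gene_rows = []
    gene_min, gene_max = cfg.gene_length_range
    per_chrom = cfg.n_promoters // cfg.n_chromosomes
    remainder = cfg.n_promoters - per_chrom * cfg.n_chromosomes
    gidx = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(BASES, size=chrom_len, p=probs).tobytes().decode()
        genome[chrom] = seq
        n_prom = per_chrom + (1 if ci < remainder else 0)
        if n_prom == 0:
            continue
        slot = chrom_len // n_prom
        if slot < 2000:
            raise ValueError("promoters unplaceable at requested density")
        for si in range(n_prom):
            lo = si * slot + slot // 4
            hi = si * slot + slot // 2
            pos = int(rng.integers(lo, hi))
            gidx += 1
            pid, gid = f"P{gidx:05d}", f"G{gidx:05d}"
            glen = int(rng.integers(gene_min, gene_max))
            tss_rows.append((chrom, pos, "+", pid, gid))
            gene_rows.append((chrom, pos, min(pos + glen, chrom_len), gid))
    tss_table = pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "promoter_id", "gene_id"])
    gene_annotation = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"])
    return genome, tss_table, gene_annotation


def _sample_decay_distance(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    """Inverse-CDF sample from p(d) ~ d^-alpha on [decay_min, decay_max]."""
    u = rng.random(n)
    a, lo, hi = cfg.decay_alpha, float(cfg.decay_min), float(cfg.decay_max)
    if abs(a - 1.0) < 1e-9:
        return (lo * (hi / lo) ** u).astype(np.int64)
    exp = 1.0 - a
    return ((lo**exp + u * (hi**exp - lo**exp)) ** (1.0 / exp)).astype(np.int64)


def _plant_loops(
    rng: np.random.Generator,
    cfg: SimConfig,
    fragmap: FragmentMap,
    targets: ProbeTargetSet,
    tss_table: pd.DataFrame,
) -> pd.DataFrame:
    target_index = GenomicIntervals(targets.frame)
    span = targets.promoter_span().set_index("promoter_id")
    rows = []
    used: set[tuple[str, str]] = set()
    promoters = tss_table.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    attempts = 0
    i = 0
    while len(rows) < cfg.n_planted_loops and attempts < 50 * cfg.n_planted_loops:
        attempts += 1
        if rows and rng.random() < cfg.shared_enhancer_fraction:
            # reuse an earlier distal fragment with a different nearby promoter
            prev = rows[int(rng.integers(0, len(rows)))]
            mid = (prev["frag_start"] + prev["frag_end"]) // 2
            nearby = tss_table[
                (tss_table["chrom"] == prev["chrom"])
                & ((tss_table["pos"] - mid).abs() >= cfg.loop_distance_min)
                & ((tss_table["pos"] - mid).abs() <= cfg.loop_distance_max)
                & (tss_table["promoter_id"] != prev["promoter_id"])
            ]
            if nearby.empty:
                continue
            prom = nearby.iloc[int(rng.integers(0, len(nearby)))]
            chrom, fs, fe = prev["chrom"], prev["frag_start"], prev["frag_end"]
        else:
            prom = promoters.iloc[i % len(promoters)]
            i += 1
            chrom = str(prom["chrom"])
            chrom_len = fragmap.chrom_length(chrom)
            d = float(np.exp(rng.normal(cfg.loop_distance_logmu, cfg.loop_distance_sigma)))
            d = int(min(max(d, cfg.loop_distance_min), cfg.loop_distance_max))
            side = 1 if rng.random() < 0.5 else -1
            pos = int(prom["pos"]) + side * d
            if pos < 0 or pos >= chrom_len:
                continue
            c, fs, fe = fragmap.locate(chrom, pos)
            if len(target_index.query(chrom, fs, fe)) > 0:
                continue  # distal fragment must not carry any probe
        frag = fragment_id(chrom, fs, fe)
        key = (str(prom["promoter_id"]), frag)
        if key in used:
            continue
        used.add(key)
        sp = span.loc[prom["promoter_id"]]
        mid = (fs + fe) // 2
        rows.append(
            {
                "promoter_id": prom["promoter_id"],
                "gene_id": prom["gene_id"],
                "chrom": chrom,
                "tss_pos": int(prom["pos"]),
                "frag_id": frag,
                "frag_start": fs,
                "frag_end": fe,
                "distance": abs(mid - int(sp["midpoint"])),
            }
        )
    return pd.DataFrame(rows)


def _promoter_target_regions(targets: ProbeTargetSet) -> dict[str, list[tuple[str, int, int]]]:
    regions: dict[str, list[tuple[str, int, int]]] = {}
    for row in targets.frame.itertuples(index=False):
        for pid in row.promoter_ids:
            regions.setdefault(pid, []).append((row.chrom, int(row.start), int(row.end)))
    return regions


def simulate_reads(
    cfg: SimConfig,
    fragmap: FragmentMap,
    targets: ProbeTargetSet,
    tss_table: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Per-replicate aligned-end tables plus the planted ground truth."""
    rng = np.random.default_rng(cfg.seed + 1)
    chroms = fragmap.chroms
    lengths = np.array([fragmap.chrom_length(c) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    prom_regions = _promoter_target_regions(targets)
    loops = _plant_loops(rng, cfg, fragmap, targets, tss_table)

    prom_ids = list(prom_regions)
    pp_rows = []
    for _ in range(cfg.n_planted_pp):
        a, b = rng.choice(len(prom_ids), size=2, replace=False)
        pp_rows.append(tuple(sorted((prom_ids[a], prom_ids[b]))))
    pp_contacts = pd.DataFrame(sorted(set(pp_rows)), columns=["promoter1", "promoter2"])

    ee_rows = []
    if len(loops) >= 2:
        frag_pool = list(dict.fromkeys(loops["frag_id"]))
        for _ in range(cfg.n_planted_ee):
            a, b = rng.choice(len(frag_pool), size=2, replace=False)
            ee_rows.append(tuple(sorted((frag_pool[a], frag_pool[b]))))
    ee_contacts = pd.DataFrame(sorted(set(ee_rows)), columns=["frag1", "frag2"])

    def uniform_in_regions(regions: list[tuple[str, int, int]]) -> tuple[str, int]:
        widths = np.array([e - s for _, s, e in regions], dtype=float)
        i = int(rng.choice(len(regions), p=widths / widths.sum()))
        c, s, e = regions[i]
        return c, int(rng.integers(s, e))

    def uniform_in_frag(frag: str) -> tuple[str, int]:
        c, s, e = fm.parse_fragment_id(frag)
        return c, int(rng.integers(s, e))

    ends_by_rep: dict[str, pd.DataFrame] = {}
    for rep_i in range(cfg.n_replicates):
        rep = f"rep{rep_i + 1}"
        rec: list[tuple[str, int, str, int]] = []  # chrom1,pos1,chrom2,pos2

        for row in loops.itertuples(index=False):
            for _ in range(rng.poisson(cfg.loop_rate)):
                c1, p1 = uniform_in_regions(prom_regions[row.promoter_id])
                c2, p2 = uniform_in_frag(row.frag_id)
                rec.append((c1, p1, c2, p2))
        for row in pp_contacts.itertuples(index=False):
            for _ in range(rng.poisson(cfg.pp_rate)):
                c1, p1 = uniform_in_regions(prom_regions[row.promoter1])
                c2, p2 = uniform_in_regions(prom_regions[row.promoter2])
                rec.append((c1, p1, c2, p2))
        for row in ee_contacts.itertuples(index=False):
            for _ in range(rng.poisson(cfg.ee_rate)):
                c1, p1 = uniform_in_frag(row.frag1)
                c2, p2 = uniform_in_frag(row.frag2)
                rec.append((c1, p1, c2, p2))

        # background with distance decay, mild capture bias and trans noise
        n_bg = cfg.pairs_per_replicate
        if n_bg > 0:
            ci = rng.choice(len(chroms), size=n_bg, p=weights)
            pos1 = (rng.random(n_bg) * lengths[ci]).astype(np.int64)
            chrom1 = np.array(chroms, dtype=object)[ci]
            biased = rng.random(n_bg) < cfg.capture_bias
            if biased.any():
                all_regions = [r for regs in prom_regions.values() for r in regs]
                widths = np.array([e - s for _, s, e in all_regions], dtype=float)
                probs = widths / widths.sum()
                picks = rng.choice(len(all_regions), size=int(biased.sum()), p=probs)
                bpos = np.array(
                    [int(rng.integers(all_regions[k][1], all_regions[k][2])) for k in picks]
                )
                bchrom = np.array([all_regions[k][0] for k in picks], dtype=object)
                pos1[biased] = bpos
                chrom1[biased] = bchrom
            is_trans = rng.random(n_bg) < cfg.trans_fraction
            d = _sample_decay_distance(rng, cfg, n_bg)
            side = rng.choice([-1, 1], size=n_bg)
            clen1 = np.array([fragmap.chrom_length(c) for c in chrom1], dtype=np.int64)
            pos2 = np.clip(pos1 + side * d, 0, clen1 - 1)
            cj = rng.choice(len(chroms), size=n_bg, p=weights)
            chrom2 = np.where(is_trans, np.array(chroms, dtype=object)[cj], chrom1)
            clen2 = np.array([fragmap.chrom_length(c) for c in chrom2], dtype=np.int64)
            tpos = (rng.random(n_bg) * clen2).astype(np.int64)
            pos2 = np.where(is_trans, tpos, pos2)
            rec.extend(zip(chrom1.tolist(), pos1.tolist(), chrom2.tolist(), pos2.tolist()))

        pairs = pd.DataFrame(rec, columns=["chrom1", "pos1", "chrom2", "pos2"])
        pairs["strand1"] = np.where(rng.random(len(pairs)) < 0.5, "+", "-")
        pairs["strand2"] = np.where(rng.random(len(pairs)) < 0.5, "+", "-")
        n_dup = int(cfg.duplicate_rate * len(pairs))
        if n_dup > 0:
            dup = pairs.sample(n=n_dup, replace=True, random_state=int(rng.integers(2**31)))
            pairs = pd.concat([pairs, dup], ignore_index=True)
        pairs = pairs.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
        read_ids = [f"{rep}_r{i}" for i in range(len(pairs))]
        ends = pd.DataFrame(
            {
                "read_id": read_ids + read_ids,
                "chrom": pd.concat([pairs["chrom1"], pairs["chrom2"]], ignore_index=True),
                "pos": pd.concat([pairs["pos1"], pairs["pos2"]], ignore_index=True),
                "strand": pd.concat([pairs["strand1"], pairs["strand2"]], ignore_index=True),
            }
        )
        ends_by_rep[rep] = ends

    truth = GroundTruth(loops=loops, pp_contacts=pp_contacts, ee_contacts=ee_contacts)
    return ends_by_rep, truth


def _simulate_tads(rng: np.random.Generator, cfg: SimConfig, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    rows = []
    lo, hi = cfg.tad_length_range
    glo, ghi = cfg.tad_gap_range
    for chrom, length in chrom_lengths.items():
        pos = int(rng.integers(glo, ghi + 1))
        while pos < length - lo:
            tad_len = int(rng.integers(lo, hi))
            end = min(pos + tad_len, length)
            rows.append((chrom, pos, end))
            pos = end + int(rng.integers(glo, ghi + 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_omics(
    cfg: SimConfig,
    truth: GroundTruth,
    tss_table: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    chrom_lengths: dict[str, int],
) -> dict:
    """Enhancer marks, TADs, GRO-seq-like reads, expression, TFBS, DE and GO
    tables, all consistent with the planted loops."""
    rng = np.random.default_rng(cfg.seed + 2)
    loops = truth.loops
    distal = loops.drop_duplicates("frag_id").reset_index(drop=True)

    # enhancer marks on a fraction of planted distal fragments + decoys
    marked = rng.random(len(distal)) < cfg.enhancer_mark_fraction
    mark_rows = [
        (r.chrom, max(0, r.frag_start - 100), r.frag_end + 100, float(rng.uniform(10, 100)))
        for r, m in zip(distal.itertuples(index=False), marked)
        if m
    ]
    chroms = list(chrom_lengths)
    clens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    cw = clens / clens.sum()
    for _ in range(cfg.n_decoy_marks):
        ci = int(rng.choice(len(chroms), p=cw))
        start = int(rng.integers(0, chrom_lengths[chroms[ci]] - 500))
        mark_rows.append((chroms[ci], start, start + 500, float(rng.uniform(1, 50))))
    enhancer_marks = pd.DataFrame(mark_rows, columns=["chrom", "start", "end", "score"])

    tads = _simulate_tads(rng, cfg, chrom_lengths)

    # expression: gene RPKM log-normal; distal RPKM correlated via shared latent
    genes = tss_table[["gene_id"]].copy()
    z_gene = rng.normal(size=len(genes))
    genes["rpkm"] = np.exp(1.0 + 1.0 * z_gene)
    gene_rpkm = genes.rename(columns={"gene_id": "gene_id"})
    z_map = dict(zip(tss_table["gene_id"], z_gene))
    c = cfg.expression_correlation
    # one expression value per distal region; shared regions track the mean
    # latent of their connected genes
    frag_genes: dict[str, list[str]] = {}
    for row in loops.itertuples(index=False):
        frag_genes.setdefault(row.frag_id, []).append(row.gene_id)
    distal_rows = []
    for frag, gene_list in frag_genes.items():
        zbar = float(np.mean([z_map[g] for g in gene_list]))
        z = c * zbar + math.sqrt(max(1 - c * c, 0.0)) * rng.normal()
        distal_rows.append((frag, float(np.exp(0.5 + z))))
    distal_rpkm = pd.DataFrame(distal_rows, columns=["region_id", "rpkm"])

    # GRO-seq-like reads: signal at planted enhancers scaled by distal RPKM
    rpkm_by_frag = distal_rpkm.set_index("region_id")["rpkm"]
    read_rows = []
    for row in distal.itertuples(index=False):
        lam = cfg.erna_signal * rpkm_by_frag.get(row.frag_id, 1.0) * (row.frag_end - row.frag_start) / 1000.0
        n = rng.poisson(lam)
        for p in rng.integers(row.frag_start, row.frag_end, size=n):
            read_rows.append((row.chrom, int(p)))
    n_noise = rng.poisson(cfg.erna_noise * sum(chrom_lengths.values()) / 1000.0)
    ci = rng.choice(len(chroms), size=n_noise, p=cw)
    for i in range(n_noise):
        read_rows.append((chroms[ci[i]], int(rng.random() * chrom_lengths[chroms[ci[i]]])))
    gro_reads = pd.DataFrame(read_rows, columns=["chrom", "pos"])

    # TF binding and perturbation response
    loops_by_frag: dict[str, set[str]] = {}
    for row in loops.itertuples(index=False):
        loops_by_frag.setdefault(row.frag_id, set()).add(row.gene_id)
    all_genes = list(tss_table["gene_id"])
    tfbs: dict[str, pd.DataFrame] = {}
    de_tables: dict[str, pd.DataFrame] = {}
    tf_targets: dict[str, set[str]] = {}
    upregulated: dict[str, set[str]] = {}
    for ti in range(cfg.n_tfs):
        tf = f"TF{ti + 1}"
        bound = distal[rng.random(len(distal)) < cfg.tf_bind_fraction]
        peak_rows = [
            (r.chrom, max(0, (r.frag_start + r.frag_end) // 2 - 50), (r.frag_start + r.frag_end) // 2 + 50, float(rng.uniform(10, 100)))
            for r in bound.itertuples(index=False)
        ]
        for _ in range(cfg.n_decoy_peaks):
            cj = int(rng.choice(len(chroms), p=cw))
            start = int(rng.integers(0, chrom_lengths[chroms[cj]] - 100))
            peak_rows.append((chroms[cj], start, start + 100, float(rng.uniform(1, 50))))
        tfbs[tf] = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "score"])
        targets_genes: set[str] = set()
        for frag in bound["frag_id"]:
            targets_genes |= loops_by_frag.get(frag, set())
        tf_targets[tf] = targets_genes
        p_up = np.full(len(all_genes), cfg.baseline_up_rate)
        target_mask = np.array([g in targets_genes for g in all_genes])
        p_up[target_mask] = np.minimum(cfg.baseline_up_rate * cfg.up_effect_size, 1.0)
        is_up = rng.random(len(all_genes)) < p_up
        fc = np.where(is_up, rng.uniform(1.6, 4.0, len(all_genes)), rng.uniform(0.7, 1.4, len(all_genes)))
        fdr = np.where(is_up, rng.uniform(0.0, 0.049, len(all_genes)), rng.uniform(0.06, 1.0, len(all_genes)))
        de_tables[tf] = pd.DataFrame({"gene_id": all_genes, "fold_change": fc, "fdr": fdr})
        upregulated[tf] = {g for g, u in zip(all_genes, is_up) if u}

    # GO table: random terms plus shared terms on planted PP pairs
    go_rows = []
    terms = [f"GO:{i:07d}" for i in range(cfg.n_go_terms)]
    for g in all_genes:
        for t in rng.choice(terms, size=int(rng.integers(1, 4)), replace=False):
            go_rows.append((g, t))
    prom_gene = dict(zip(tss_table["promoter_id"], tss_table["gene_id"]))
    for row in truth.pp_contacts.itertuples(index=False):
        if rng.random() < cfg.go_shared_fraction:
            t = terms[int(rng.integers(0, len(terms)))]
            go_rows.append((prom_gene[row.promoter1], t))
            go_rows.append((prom_gene[row.promoter2], t))
    go_table = pd.DataFrame(go_rows, columns=["gene_id", "term"]).drop_duplicates().reset_index(drop=True)

    truth.enhancer_marks = enhancer_marks
    truth.tads = tads
    truth.tf_targets = tf_targets
    truth.upregulated = upregulated
    return {
        "enhancer_marks": enhancer_marks,
        "tads": tads,
        "gro_reads": gro_reads,
        "gene_rpkm": gene_rpkm,
        "distal_rpkm": distal_rpkm,
        "tfbs": tfbs,
        "de_tables": de_tables,
        "go_table": go_table,
    }


def calls_from_truth(data: "SimData", support: int = 3) -> pd.DataFrame:
    """Oracle interaction table straight from the planted ground truth,
    bypassing read simulation — the ideal caller output for testing the
    statistical modules at scale."""
    span = data.targets.promoter_span().set_index("promoter_id")
    rows = []
    for row in data.truth.loops.itertuples(index=False):
        sp = span.loc[row.promoter_id]
        rows.append(
            (
                "PD", row.promoter_id, row.frag_id, row.gene_id,
                sp["chrom"], int(sp["start"]), int(sp["end"]),
                row.chrom, int(row.frag_start), int(row.frag_end),
                False, float(row.distance), support, support,
            )
        )
    for row in data.truth.pp_contacts.itertuples(index=False):
        a, b = span.loc[row.promoter1], span.loc[row.promoter2]
        trans = a["chrom"] != b["chrom"]
        distance = float("nan") if trans else float(abs(int(b["midpoint"]) - int(a["midpoint"])))
        gene = data.tss_table.set_index("promoter_id").loc[row.promoter1, "gene_id"]
        rows.append(
            (
                "PP", row.promoter1, row.promoter2, gene,
                a["chrom"], int(a["start"]), int(a["end"]),
                b["chrom"], int(b["start"]), int(b["end"]),
                trans, distance, support, support,
            )
        )
    for row in data.truth.ee_contacts.itertuples(index=False):
        c1, s1, e1 = fm.parse_fragment_id(row.frag1)
        c2, s2, e2 = fm.parse_fragment_id(row.frag2)
        trans = c1 != c2
        distance = float("nan") if trans else float(abs((s2 + e2) // 2 - (s1 + e1) // 2))
        rows.append(
            ("DD", row.frag1, row.frag2, "", c1, s1, e1, c2, s2, e2, trans, distance, support, support)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "type", "anchor", "partner", "gene_id",
            "anchor_chrom", "anchor_start", "anchor_end",
            "partner_chrom", "partner_start", "partner_end",
            "trans", "distance", "support_rep1", "support_rep2",
        ],
    )


def simulate_all(cfg: SimConfig, with_omics: bool = True) -> SimData:
    """Genome -> digestion -> probe design -> reads -> omics, in one call."""
    genome, tss_table, gene_annotation = simulate_genome(cfg)
    fragmap = fm.digest(genome, "GATC")
    targets = fm.design_probe_targets(tss_table, fragmap)
    ends_by_rep, truth = simulate_reads(cfg, fragmap, targets, tss_table)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    data = SimData(
        config=cfg,
        genome=genome,
        chrom_lengths=chrom_lengths,
        tss_table=tss_table,
        gene_annotation=gene_annotation,
        fragmap=fragmap,
        targets=targets,
        ends_by_replicate=ends_by_rep,
        truth=truth,
    )
    if with_omics:
        omics = simulate_omics(cfg, truth, tss_table, gene_annotation, chrom_lengths)
        data.enhancer_marks = omics["enhancer_marks"]
        data.tads = omics["tads"]
        data.gro_reads = omics["gro_reads"]
        data.gene_rpkm = omics["gene_rpkm"]
        data.distal_rpkm = omics["distal_rpkm"]
        data.tfbs = omics["tfbs"]
        data.de_tables = omics["de_tables"]
        data.go_table = omics["go_table"]
    return data
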