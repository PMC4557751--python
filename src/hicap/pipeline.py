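"""Pipeline configuration and the end-to-end runner.

The configuration is a flat YAML key-value file; every stage's numeric
threshold has a default matching the published workflow (min_support=3,
min_distance=1000, flank=150, merge_below=300, top_k=5000, min_len=1000,
fdr_max=0.05, fc_min=1.5). All randomness flows from a single seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment, fragmap as fm, interactions, io, network, pairs as pr, perturbation, simulate

logger = logging.getLogger("hicap")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "hicap_out"
    # inputs; when fasta is None the simulator provides everything
    fasta: str | None = None
    tss: str | None = None
    ends: dict[str, str] = field(default_factory=dict)  # replicate -> path
    enhancers: str | None = None
    tads: str | None = None
    site: str = "GATC"
    flank: int = 150
    merge_below: int = 300
    min_distance: int = 1000
    min_support: int = 3
    top_k: int = 5000
    min_len: int = 1000
    fdr_max: float = 0.05
    fc_min: float = 1.5
    rpkm_thresholds: tuple[float, float] = (0.1, 1.0)
    expressed_rpkm: float = 3.0
    silent_rpkm: float = 0.3
    simulate: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: ["call"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _check_inputs(cfg: PipelineConfig) -> None:
    for label, path in [("fasta", cfg.fasta), ("tss", cfg.tss)]:
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{label} input missing: {path}")
    for rep, path in cfg.ends.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"ends input for {rep} missing: {path}")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute digest -> probes -> filter -> call (plus any requested
    downstream stages) and write versioned outputs and a run log."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": {k: v for k, v in asdict(cfg).items() if k != "ends"} | {"ends": dict(cfg.ends)}}

    if cfg.fasta is None:
        sim_cfg = simulate.SimConfig(seed=cfg.seed, **cfg.simulate)
        data = simulate.simulate_all(sim_cfg)
        genome = data.genome
        tss_table = data.tss_table
        ends_by_rep = data.ends_by_replicate
        io.write_fasta(genome, out / "genome.fa")
        tss_bed = pd.DataFrame(
            {
                "chrom": tss_table["chrom"],
                "start": tss_table["pos"],
                "end": tss_table["pos"] + 1,
                "name": tss_table["promoter_id"] + "|" + tss_table["gene_id"],
            }
        )
        io.write_bed(tss_bed, out / "tss.bed")
        for rep, ends in ends_by_rep.items():
            io.write_ends(ends, out / f"ends_{rep}.tsv")
        log["simulated"] = {"n_planted_loops": int(len(data.truth.loops))}
    else:
        _check_inputs(cfg)
        genome = io.read_fasta(cfg.fasta)
        tss_bed = io.read_bed(cfg.tss)
        names = tss_bed["name"].astype(str).str.split("|", expand=True)
        tss_table = pd.DataFrame(
            {
                "chrom": tss_bed["chrom"],
                "pos": tss_bed["start"],
                "strand": "+",
                "promoter_id": names[0],
                "gene_id": names[1] if names.shape[1] > 1 else names[0],
            }
        )
        ends_by_rep = {rep: io.read_ends(path) for rep, path in cfg.ends.items()}
        data = None

    fragmap = fm.digest(genome, cfg.site)
    io.write_fragments_bed(fragmap, out / "fragments.bed")
    targets = fm.design_probe_targets(tss_table, fragmap, flank=cfg.flank, merge_below=cfg.merge_below)
    io.write_probes_bed(targets, out / "probes.bed")
    log["digest"] = {
        "n_fragments": int(fragmap.n_fragments()),
        "mean_fragment_length": fm.mean_fragment_length(fragmap),
        "n_probe_targets": int(len(targets)),
    }

    retained_by_rep: dict[str, pd.DataFrame] = {}
    valid_by_rep: dict[str, pd.DataFrame] = {}
    log["filter"] = {}
    for rep, ends in ends_by_rep.items():
        retained, report = pr.filter_pairs(ends, fragmap, targets, min_distance=cfg.min_distance)
        if not report.conserved():
            raise AssertionError(f"pair-count conservation violated for {rep}")
        retained_by_rep[rep] = retained
        paired, _ = pr.pair_ends(ends)
        deduped, _ = pr.dedupe(paired)
        classified = pr.classify(deduped, fragmap, min_distance=cfg.min_distance)
        valid_by_rep[rep] = classified[classified["validity_class"] == "valid"].reset_index(drop=True)
        log["filter"][rep] = report.as_dict()

    counts = interactions.count_support(retained_by_rep, targets)
    calls = interactions.call_interactions(counts, targets, min_support=cfg.min_support)
    dd = interactions.call_dd(valid_by_rep, calls, min_support=cfg.min_support)
    all_calls = pd.concat([calls, dd], ignore_index=True)
    all_calls = interactions.annotate_closest_gene(all_calls, tss_table)
    io.write_calls(all_calls, out / "calls.tsv")
    io.write_interactions_gff(all_calls, out / "calls.gff")
    log["call"] = {
        "n_calls": int(len(all_calls)),
        "n_pd": int((all_calls["type"] == "PD").sum()),
        "n_pp": int((all_calls["type"] == "PP").sum()),
        "n_dd": int((all_calls["type"] == "DD").sum()),
    }

    if data is not None and len(data.truth.loops):
        called = set(zip(calls.loc[calls["type"] == "PD", "anchor"], calls.loc[calls["type"] == "PD", "partner"]))
        planted = set(zip(data.truth.loops["promoter_id"], data.truth.loops["frag_id"]))
        tp = len(called & planted)
        log["ground_truth"] = {
            "n_planted": len(planted),
            "n_called_pd": len(called),
            "recall": tp / len(planted) if planted else float("nan"),
            "precision": tp / len(called) if called else float("nan"),
        }

    if "network" in cfg.stages:
        net = network.build_network(all_calls)
        stats = network.degree_stats(net)
        motifs = network.count_motifs(net, backgrounds=network.randomize_edges(net, n_rounds=5, seed=cfg.seed))
        io.write_tsv(motifs, out / "motifs.tsv")
        log["network"] = {
            "mean_promoters_per_enhancer": stats["mean_promoters_per_enhancer"],
            "mean_enhancers_per_promoter": stats["mean_enhancers_per_promoter"],
        }
    if "enrich" in cfg.stages and data is not None and data.enhancer_marks is not None:
        features = enrichment.prepare_features(data.enhancer_marks, top_k=cfg.top_k, min_len=cfg.min_len)
        pd_calls = all_calls[(all_calls["type"] == "PD") & (~all_calls["trans"])]
        regions = pd_calls.rename(
            columns={"partner_chrom": "chrom", "partner_start": "start", "partner_end": "end"}
        )[["chrom", "start", "end"]]
        background = enrichment.sample_background(all_calls, tss_table, len(regions) * 5, cfg.seed)
        result = enrichment.overlap_signal(regions, features, background, name="enhancer_marks")
        log["enrich"] = {"signal": result.signal, "chi2_p": result.chi2_p}

    with open(out / "run_log.json", "w") as handle:
        json.dump(log, handle, indent=2, default=str)
    return out
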