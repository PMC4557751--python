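# hicap

A toolkit for promoter-capture Hi-C analysis: in-silico restriction
digestion and capture-probe design, read-pair filtering, replicate-thresholded
interaction calling, and the downstream statistics used to characterise
promoter-anchored regulatory interactions — feature-overlap enrichment against
a distance-matched background, TAD containment, enhancer-RNA expression,
TF-perturbation validation, and interaction-network motif/clique analysis.
A simulator generates every input format with planted ground truth, so the
whole pipeline is testable offline.

## Layout

| module | purpose |
| --- | --- |
| `hicap.fragmap` | genome digestion at a recognition site (default MboI `GATC`), probe-target design around TSSs |
| `hicap.pairs` | end pairing, duplicate removal, self-ligation filtering (<1 kb), on-target filtering, capture statistics |
| `hicap.interactions` | read-support counting and calling (≥3 reads in every replicate), PP and DD calls, closest-gene annotation |
| `hicap.enrichment` | top-5000 feature preparation, distance-matched background sampling, overlap signal + χ², TAD containment, RPKM, eRNA and expression-correlation analyses |
| `hicap.perturbation` | DE gene selection (FDR ≤ 0.05, FC > 1.5), closest/connected gene sets, fold improvement `[Uh/Nh]/[Uc/Nc]`, compound and Fisher split tests |
| `hicap.network` | typed promoter/enhancer graphs, degree-preserving per-class randomization, motif counts, maximal cliques, same-TF subnetwork degree, GO pair sharing, support-vs-shared-enhancer Wilcoxon/Stouffer |
| `hicap.simulate` | seeded synthetic genomes, reads with distance decay + planted loops, omics tracks |
| `hicap.io`, `hicap.pipeline`, `hicap.cli` | FASTA/BED/TSV/SAM/GFF readers and writers, YAML-configured pipeline, `hicap` CLI |

## CLI

```bash
# simulate a dataset with planted loops
hicap simulate --seed 1 --genome-length 2000000 --n-promoters 60 --out sim/

# stage by stage
hicap digest --fasta sim/genome.fa --site GATC --out frags.bed
hicap design-probes --tss sim/tss.bed --frags frags.bed --flank 150 --merge-below 300 --out probes.bed
hicap filter-pairs --ends sim/ends_rep1.tsv --frags frags.bed --probes probes.bed --min-dist 1000 --out pairs1.tsv
hicap filter-pairs --ends sim/ends_rep2.tsv --frags frags.bed --probes probes.bed --min-dist 1000 --out pairs2.tsv
hicap call --pairs pairs1.tsv --pairs pairs2.tsv --probes probes.bed --min-support 3 --out calls.tsv
hicap network --calls calls.tsv --out motifs.tsv

# or the whole pipeline from one YAML config
hicap run --config pipeline.yaml
```

A minimal `pipeline.yaml` (omitting `fasta` makes the simulator provide all
inputs):

```yaml
seed: 11
out_dir: out
simulate:
  genome_length: 2000000
  n_promoters: 60
stages: [call, network]
```

Outputs are TSV/BED plus a browser-style GFF of interactions and a
`run_log.json` with per-filter class counts (input = retained + duplicate +
too_close + same_fragment + off_target is asserted on every run).

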