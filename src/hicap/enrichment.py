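"""Feature-overlap enrichment against a distance-matched background, TAD
containment, and enhancer-RNA expression analyses of distal regions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GenomicIntervals
from .stats import chi2_two_proportions, permutation_pvalue

__all__ = [
    "prepare_features",
    "sample_background",
    "overlap_signal",
    "tad_containment",
    "region_rpkm",
    "erna_analysis",
    "expression_correlation",
    "EnrichmentResult",
]


@dataclass
class EnrichmentResult:
    feature: str
    n_observed: int
    n_background: int
    observed_fraction: float
    expected_fraction: float
    signal: float | None
    chi2: float
    chi2_p: float


def prepare_features(
    raw: pd.DataFrame, top_k: int = 5000, min_len: int = 1000
) -> pd.DataFrame:
    """Keep the `top_k` highest-scoring intervals; symmetrically extend any
    interval shorter than `min_len` to `min_len` around its midpoint."""
    features = raw.copy()
    if len(features) > top_k:
        if "score" not in features.columns or features["score"].isna().any():
            raise ValueError("scores required to select top-k features")
        features = features.nlargest(top_k, "score")
    features = features.reset_index(drop=True)
    length = features["end"] - features["start"]
    short = length < min_len
    if short.any():
        mid = (features.loc[short, "start"] + features.loc[short, "end"]) // 2
        features.loc[short, "start"] = np.maximum(mid - min_len // 2, 0)
        features.loc[short, "end"] = features.loc[short, "start"] + min_len
    return features


def _finite_distances(calls: pd.DataFrame) -> np.ndarray:
    mask = (calls["type"] == "PD") & (~calls["trans"].astype(bool))
    d = calls.loc[mask, "distance"].to_numpy(dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no same-chromosome PD calls with finite distances")
    return d


def sample_background(
    calls: pd.DataFrame,
    tss_table: pd.DataFrame,
    n_samples: int,
    seed: int,
    lengths: np.ndarray | None = None,
) -> pd.DataFrame:
    """Distance-matched random regions around annotated TSSs.

    Each sample draws a random TSS, a distance resampled from the observed
    PD-interaction distance distribution, a random side, and a length
    resampled from the observed distal-fragment lengths (or `lengths` when
    given). Regions are clipped to [0, inf); reproducible from `seed`.
    """
    rng = np.random.default_rng(seed)
    distances = _finite_distances(calls)
    if lengths is None:
        pd_calls = calls[(calls["type"] == "PD") & (~calls["trans"])]
        lengths = (pd_calls["partner_end"] - pd_calls["partner_start"]).to_numpy()
    tss_idx = rng.integers(0, len(tss_table), size=n_samples)
    dist = rng.choice(distances, size=n_samples, replace=True)
    side = rng.choice([-1, 1], size=n_samples)
    length = rng.choice(np.asarray(lengths), size=n_samples, replace=True).astype(int)
    tss_pos = tss_table["pos"].to_numpy()[tss_idx]
    centers = tss_pos + side * dist.astype(int)
    starts = np.maximum(centers - length // 2, 0)
    return pd.DataFrame(
        {
            "chrom": tss_table["chrom"].to_numpy()[tss_idx],
            "start": starts,
            "end": starts + length,
            "distance": dist,
        }
    )


def overlap_signal(
    regions: pd.DataFrame,
    features: pd.DataFrame,
    background: pd.DataFrame,
    name: str = "feature",
) -> EnrichmentResult:
    """Observed vs expected fraction of regions overlapping features by >=1 bp.

    The expected fraction comes from the background regions; the p-value is a
    1-df chi-square goodness-of-fit of the observed overlap count against the
    expected fraction.
    """
    if len(regions) == 0 or len(background) == 0:
        raise ValueError("regions and background must be non-empty")
    index = GenomicIntervals(features)
    n_obs = int(index.overlap_flags(regions).sum())
    n_exp = int(index.overlap_flags(background).sum())
    obs_frac = n_obs / len(regions)
    exp_frac = n_exp / len(background)
    if exp_frac == 0.0:
        return EnrichmentResult(
            name, len(regions), len(background), obs_frac, 0.0, None, float("nan"), float("nan")
        )
    # chi2 needs an expected fraction strictly inside (0,1); signal uses it raw
    exp_for_chi2 = min(exp_frac, 1.0 - 1.0 / (2 * len(background)))
    chi2, p = chi2_two_proportions(n_obs, len(regions), exp_for_chi2)
    return EnrichmentResult(
        name, len(regions), len(background), obs_frac, exp_frac, obs_frac / exp_frac, chi2, p
    )


def _containment_class(
    tads: GenomicIntervals, chrom: str, a_start: int, a_end: int, b_start: int, b_end: int
) -> str:
    def containing(start: int, end: int) -> int | None:
        for r in tads.query(chrom, start, end):
            row = tads.frame.iloc[r]
            if row["start"] <= start and end <= row["end"]:
                return int(r)
        return None

    ta = containing(a_start, a_end)
    tb = containing(b_start, b_end)
    if ta is None or tb is None:
        return "outside"
    return "within" if ta == tb else "spanning"


def _log2_bins(max_distance: float) -> list[tuple[float, float]]:
    bins = []
    lo = 1000.0
    while lo <= max_distance:
        bins.append((lo, lo * 2))
        lo *= 2
    return bins or [(1000.0, 2000.0)]


def tad_containment(
    calls: pd.DataFrame,
    tads: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bins: list[tuple[float, float]] | None = None,
    n_control: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify same-chromosome calls as within / spanning / outside TADs per
    distance bin and compare with distance-preserving random controls.

    Controls reassign each interaction to a random chromosome and position
    while keeping the anchor-partner distance and region lengths. Per bin and
    class a 1-df chi-square compares observed counts with the control
    fraction; the highest p across the three classes is reported as `max_p`.
    """
    cis = calls[~calls["trans"]].reset_index(drop=True)
    if cis.empty:
        raise ValueError("no same-chromosome calls")
    rng = np.random.default_rng(seed)
    index = GenomicIntervals(tads)
    if bins is None:
        bins = _log2_bins(float(cis["distance"].max()))

    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    def classify_frame(frame: pd.DataFrame) -> pd.Series:
        out = []
        for row in frame.itertuples(index=False):
            out.append(
                _containment_class(
                    index,
                    row.anchor_chrom,
                    int(row.anchor_start),
                    int(row.anchor_end),
                    int(row.partner_start),
                    int(row.partner_end),
                )
            )
        return pd.Series(out, index=frame.index)

    observed_cls = classify_frame(cis)

    control_frames = []
    for _ in range(n_control):
        ctrl = cis.copy()
        ci = rng.choice(len(chroms), size=len(ctrl), p=weights)
        span = (ctrl["partner_end"].to_numpy() - ctrl["anchor_start"].to_numpy()).astype(int)
        new_chrom = [chroms[i] for i in ci]
        max_start = np.maximum(lengths[ci].astype(int) - np.abs(span) - 1, 1)
        new_start = (rng.random(len(ctrl)) * max_start).astype(int)
        a_len = (ctrl["anchor_end"] - ctrl["anchor_start"]).to_numpy()
        gap = (ctrl["partner_start"] - ctrl["anchor_start"]).to_numpy()
        p_len = (ctrl["partner_end"] - ctrl["partner_start"]).to_numpy()
        ctrl["anchor_chrom"] = new_chrom
        ctrl["partner_chrom"] = new_chrom
        ctrl["anchor_start"] = new_start
        ctrl["anchor_end"] = new_start + a_len
        ctrl["partner_start"] = new_start + np.abs(gap)
        ctrl["partner_end"] = ctrl["partner_start"] + p_len
        control_frames.append(ctrl)
    control = pd.concat(control_frames, ignore_index=True)
    control_cls = classify_frame(control)

    rows = []
    for lo, hi in bins:
        obs_mask = (cis["distance"] >= lo) & (cis["distance"] < hi)
        ctl_mask = (control["distance"] >= lo) & (control["distance"] < hi)
        n_obs, n_ctl = int(obs_mask.sum()), int(ctl_mask.sum())
        if n_obs == 0 or n_ctl == 0:
            continue
        rec: dict = {"bin_lo": lo, "bin_hi": hi, "n_observed": n_obs, "n_control": n_ctl}
        pvals = []
        for cls in ("within", "spanning", "outside"):
            k_obs = int((observed_cls[obs_mask] == cls).sum())
            k_ctl = int((control_cls[ctl_mask] == cls).sum())
            f_obs = k_obs / n_obs
            f_ctl = k_ctl / n_ctl
            rec[f"fraction_{cls}"] = f_obs
            rec[f"expected_{cls}"] = f_ctl
            if 0.0 < f_ctl < 1.0:
                _, p = chi2_two_proportions(k_obs, n_obs, f_ctl)
            else:
                p = 1.0 if f_obs == f_ctl else 0.0
            rec[f"chi2_p_{cls}"] = p
            pvals.append(p)
        rec["max_p"] = max(pvals)
        rows.append(rec)
    return pd.DataFrame(rows)


def region_rpkm(
    regions: pd.DataFrame, reads: pd.DataFrame, total_mapped_reads: int
) -> np.ndarray:
    """RPKM = count x 1e9 / (region length x total mapped reads).

    `reads` is a table of mapped read positions (chrom, pos).
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    lengths = (regions["end"] - regions["start"]).to_numpy()
    if (lengths <= 0).any():
        raise ValueError("zero-length region")
    counts = np.zeros(len(regions), dtype=float)
    by_chrom = {str(c): np.sort(sub["pos"].to_numpy()) for c, sub in reads.groupby("chrom")}
    for i, (chrom, start, end) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        pos = by_chrom.get(str(chrom))
        if pos is None:
            continue
        counts[i] = np.searchsorted(pos, end) - np.searchsorted(pos, start)
    return counts * 1e9 / (lengths * total_mapped_reads)


def erna_analysis(
    calls: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    gro_reads: pd.DataFrame,
    tss_table: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.1, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Enhancer-RNA expression of intergenic distal regions vs matched random
    regions.

    Distal regions overlapping any annotated gene are excluded; random
    regions are distance-matched, fixed at the observed mean length, and
    rejected until they are also intergenic. Per threshold, a 1-df
    chi-square compares exceedance fractions.
    """
    genes = GenomicIntervals(gene_annotation)
    pd_calls = calls[(calls["type"] == "PD") & (~calls["trans"])].reset_index(drop=True)
    distal = pd.DataFrame(
        {
            "chrom": pd_calls["partner_chrom"],
            "start": pd_calls["partner_start"],
            "end": pd_calls["partner_end"],
        }
    ).drop_duplicates().reset_index(drop=True)
    intergenic = distal[~genes.overlap_flags(distal)].reset_index(drop=True)
    if intergenic.empty:
        raise ValueError("no intergenic distal regions")
    mean_len = int(round((intergenic["end"] - intergenic["start"]).mean()))

    rng = np.random.default_rng(seed)
    random_rows = []
    attempts = 0
    while len(random_rows) < len(intergenic) and attempts < 200 * len(intergenic):
        attempts += 1
        cand = sample_background(
            calls, tss_table, 1, int(rng.integers(0, 2**31)), lengths=np.array([mean_len])
        ).iloc[0]
        if not genes.overlaps(str(cand["chrom"]), int(cand["start"]), int(cand["end"])):
            random_rows.append(cand)
    random_regions = pd.DataFrame(random_rows).reset_index(drop=True)
    if random_regions.empty:
        raise ValueError("could not place intergenic random regions")

    total = len(gro_reads)
    rpkm_obs = region_rpkm(intergenic, gro_reads, total)
    rpkm_rnd = region_rpkm(random_regions[["chrom", "start", "end"]], gro_reads, total)

    rows = []
    for thr in thresholds:
        k_obs = int((rpkm_obs > thr).sum())
        k_rnd = int((rpkm_rnd > thr).sum())
        f_obs = k_obs / len(rpkm_obs)
        f_rnd = k_rnd / len(rpkm_rnd)
        if 0.0 < f_rnd < 1.0:
            chi2, p = chi2_two_proportions(k_obs, len(rpkm_obs), f_rnd)
        elif f_obs == f_rnd:
            chi2, p = 0.0, 1.0
        else:
            chi2, p = float("inf"), 0.0
        rows.append(
            {
                "threshold": thr,
                "n_distal": len(rpkm_obs),
                "n_random": len(rpkm_rnd),
                "fraction_distal": f_obs,
                "fraction_random": f_rnd,
                "chi2": chi2,
                "chi2_p": p,
            }
        )
    return pd.DataFrame(rows)


def expression_correlation(
    distal_rpkm: pd.DataFrame,
    gene_rpkm: pd.DataFrame,
    pairing: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Spearman correlation of distal-region and connected-gene expression
    with a label-permutation p-value.

    Multiple distal regions connected to one gene contribute their RPKM sum.
    `pairing` maps region_id -> gene_id; `distal_rpkm` has region_id, rpkm;
    `gene_rpkm` has gene_id, rpkm.
    """
    merged = pairing.merge(distal_rpkm, on="region_id").merge(
        gene_rpkm, on="gene_id", suffixes=("_distal", "_gene")
    )
    summed = merged.groupby("gene_id").agg(
        distal=("rpkm_distal", "sum"), gene=("rpkm_gene", "first")
    )
    if len(summed) < 3:
        raise ValueError("need at least 3 gene-distal pairs")
    x = summed["distal"].to_numpy()
    y = summed["gene"].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant expression vector; rho undefined")
    rho = float(sps.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_perm):
        perm_rho = sps.spearmanr(x, rng.permutation(y)).statistic
        if perm_rho >= rho:
            n_extreme += 1
    return {
        "n": int(len(summed)),
        "spearman_rho": rho,
        "perm_p": permutation_pvalue(n_extreme, n_perm),
    }
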