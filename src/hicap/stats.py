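"""Shared statistical primitives: 1-df chi-square goodness-of-fit, Stouffer
combination, Benjamini-Hochberg adjustment and permutation p-value floors."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "chi2_gof",
    "chi2_two_proportions",
    "stouffer",
    "bh_adjust",
    "permutation_pvalue",
]


def chi2_gof(observed: Sequence[float], expected: Sequence[float]) -> tuple[float, float]:
    """Chi-square goodness-of-fit without continuity correction.

    `expected` are expected counts on the same total as `observed`;
    degrees of freedom = len(observed) - 1.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(sps.chi2.sf(stat, df=len(obs) - 1))
    return stat, p


def chi2_two_proportions(k: int, n: int, expected_fraction: float) -> tuple[float, float]:
    """1-df test of an observed count k/n against an expected fraction."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 < expected_fraction < 1.0:
        raise ValueError("expected_fraction must be in (0, 1)")
    exp = [n * expected_fraction, n * (1.0 - expected_fraction)]
    return chi2_gof([k, n - k], exp)


def stouffer(z_scores: Sequence[float], two_tailed: bool = True) -> tuple[float, float]:
    """Unweighted Stouffer combination: z = sum(z_i) / sqrt(k).

    Returns (combined z, p). k identical z-scores combine to that z.
    """
    z = np.asarray(z_scores, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("no finite z-scores to combine")
    combined = float(z.sum() / np.sqrt(z.size))
    if two_tailed:
        p = float(2.0 * sps.norm.sf(abs(combined)))
    else:
        p = float(sps.norm.sf(combined))
    return combined, min(p, 1.0)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def permutation_pvalue(n_extreme: int, n_perm: int) -> float:
    """Empirical p as a fraction of permutations, floored at 1/n_perm."""
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    return min(max(n_extreme / n_perm, 1.0 / n_perm), 1.0)
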