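"""Genome-scale summary statistics: coding density, size-category detection
from a smoothed size distribution, protein-length statistics, rank tests and
the genome-size vs proteome-size regression.

The size categorizer is the objective replacement for an arbitrary genome-size
cutoff: a Gaussian kernel density estimate of genome sizes is scanned for
modes, and the valleys between retained modes become the category boundaries.
On the pooled *Caudovirales*-like size distribution this yields three
categories (small / medium / jumbo) with the upper boundary near 180 kb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.signal import find_peaks

__all__ = [
    "SizeCategoryModel",
    "LengthStats",
    "RankTestResult",
    "gene_density",
    "detect_size_categories",
    "length_stats",
    "fitted_lognormal_skewness",
    "rank_test",
    "size_regression",
    "format_pvalue",
]

#: Reporting floor for p-values, matching common statistical-software output.
P_FLOOR = 2.2e-16


@dataclass
class SizeCategoryModel:
    """Smoothed genome-size density with detected modes and valleys (kb).

    ``cutoffs`` equal the valley positions; ``n_categories`` is one more than
    the number of valleys.
    """

    bin_edges: np.ndarray
    smoothed_density: np.ndarray
    mode_positions: list[float]
    valley_positions: list[float]
    cutoffs: list[float] = field(default_factory=list)
    n_categories: int = 1

    def category_of(self, size_kb: float) -> int:
        """0-based category index for a genome size."""
        return int(np.searchsorted(self.cutoffs, size_kb))


@dataclass
class LengthStats:
    n: int
    median: float
    mean: float
    skewness: float  # NaN marks "undefined" (constant input or n < 3)


@dataclass
class RankTestResult:
    statistic: float  # Kruskal-Wallis H (tie-corrected)
    pvalue: float
    u_statistic: float | None = None  # Mann-Whitney U, two-group case only
    u_pvalue: float | None = None


def gene_density(genome) -> float:
    """Protein-coding genes per kb of genome."""
    if genome.genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    return len(genome.coding_genes) / (genome.genome_length / 1000.0)


def detect_size_categories(
    sizes_kb,
    bandwidth: float = 8.0,
    grid_step: float = 1.0,
    prominence_frac: float = 0.05,
    min_n: int = 50,
) -> SizeCategoryModel:
    """Detect genome-size categories from the valleys of a smoothed density.

    Parameters
    ----------
    sizes_kb
        Genome sizes in kb.
    bandwidth
        Gaussian kernel bandwidth in kb. The default (8 kb) resolves modes
        tens of kb apart while suppressing sampling ripple at n ~ 10^4.
    grid_step
        Evaluation grid resolution in kb.
    prominence_frac
        A local maximum is retained as a mode only if its peak prominence
        exceeds this fraction of the global density maximum.
    min_n
        Minimum sample size; valley positions from fewer genomes are too
        unstable to act as category boundaries.
    """
    sizes = np.asarray(sizes_kb, dtype=float)
    if sizes.size < min_n:
        raise ValueError(f"need at least {min_n} sizes, got {sizes.size}")
    lo = sizes.min() - 3 * bandwidth
    hi = sizes.max() + 3 * bandwidth
    grid = np.arange(lo, hi + grid_step, grid_step)
    # plain Gaussian KDE with a fixed (not data-driven) bandwidth
    z = (grid[:, None] - sizes[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (sizes.size * bandwidth * math.sqrt(2 * math.pi))
    peaks, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    if peaks.size == 0:
        raise ValueError("no mode found in the smoothed size density")
    valleys = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = dens[a : b + 1]
        valleys.append(float(grid[a + int(np.argmin(seg))]))
    modes = [float(grid[p]) for p in peaks]
    return SizeCategoryModel(
        bin_edges=grid,
        smoothed_density=dens,
        mode_positions=modes,
        valley_positions=valleys,
        cutoffs=list(valleys),
        n_categories=len(valleys) + 1,
    )


def length_stats(lengths) -> LengthStats:
    """Median (lower order statistic on even n), mean, and moment skewness
    g1 = m3 / m2^{3/2} of protein lengths.

    The lower median keeps the statistic integer-valued for aa lengths. The
    skewness is the population moment estimator; it is NaN (undefined) for
    constant input or n < 3.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one length")
    xs = np.sort(x)
    median = float(xs[(x.size - 1) // 2])
    mean = float(x.mean())
    if x.size < 3:
        skew = math.nan
    else:
        m2 = float(((x - mean) ** 2).mean())
        if m2 == 0.0:
            skew = math.nan
        else:
            m3 = float(((x - mean) ** 3).mean())
            skew = m3 / m2**1.5
    return LengthStats(n=int(x.size), median=median, mean=mean, skewness=skew)


def fitted_lognormal_skewness(lengths) -> float:
    """Moment skewness of the lognormal fitted to the lengths.

    The shape is estimated as the population SD of log-lengths and converted
    with the closed form gamma1 = (e^{sigma^2} + 2) sqrt(e^{sigma^2} - 1).
    For heavy-tailed length distributions this distributional estimate of the
    skewness concentrates far faster than the raw third-moment statistic,
    which is severely biased and noisy at realistic sample sizes.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 3 or np.any(x <= 0):
        raise ValueError("need >= 3 strictly positive lengths")
    s2 = float(np.var(np.log(x)))
    return (math.exp(s2) + 2.0) * math.sqrt(math.exp(s2) - 1.0)


def rank_test(groups) -> RankTestResult:
    """Kruskal-Wallis H (tie-corrected, chi-square p) across >= 2 groups;
    with exactly two groups the Mann-Whitney U is reported as well."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    h, p = sps.kruskal(*groups)
    u = up = None
    if len(groups) == 2:
        u, up = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        u, up = float(u), float(up)
    return RankTestResult(statistic=float(h), pvalue=float(p), u_statistic=u, u_pvalue=up)


def size_regression(genome_kb, n_proteins) -> tuple[float, float, float]:
    """OLS of proteome size on genome size; returns (slope, intercept, r2)
    with r2 the squared Pearson correlation. Constant y gives r2 = 0 by
    convention; constant x is an error."""
    x = np.asarray(genome_kb, dtype=float)
    y = np.asarray(n_proteins, dtype=float)
    if x.size != y.size:
        raise ValueError("genome_kb and n_proteins must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("genome sizes are constant; regression undefined")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def format_pvalue(p: float) -> str:
    """Report tiny p-values as a floor, the way statistical software prints
    them (e.g. "< 2.2e-16")."""
    if p < P_FLOOR:
        return f"< {P_FLOOR:g}"
    return f"{p:.3g}"
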