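"""Spatial statistics for nuclear-distance distributions.

Per-cell empirical CDFs of puncta distance to the nuclear perimeter,
cross-cell summaries (mean ± SD, median ± MAD, pooled "global" CDF),
reference CDFs for all cytosolic voxels and the cell-periphery shell, the
d50 statistic (distance within which half the signal lies), two-sample
Kolmogorov–Smirnov and Wilcoxon rank-sum tests with Bonferroni
correction, concentration-vs-distance profiles, and the total-to-
ribosome-associated density ratio arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import scipy.stats

__all__ = [
    "EmpiricalCDF",
    "CdfSummary",
    "ConcentrationProfile",
    "TestResult",
    "empirical_cdf",
    "summarize_cdfs",
    "reference_cdfs",
    "d50",
    "ks_two_sample",
    "wilcoxon_rank_sum",
    "bonferroni",
    "concentration_profile",
    "ribosome_fraction",
]

ALPHA = 0.05


@dataclass
class EmpiricalCDF:
    """Right-continuous step CDF evaluated on a uniform distance grid (µm)."""

    grid: np.ndarray
    values: np.ndarray
    n_observations: int
    sample: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.grid.size != self.values.size:
            raise ValueError("grid and values must align")
        if self.grid.size > 1:
            steps = np.diff(self.grid)
            if np.any(steps <= 0):
                raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("CDF must be nondecreasing")

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else 0.0

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Linear interpolation onto arbitrary distances (clamped to [0, 1])."""
        return np.interp(x, self.grid, self.values, left=self.values[0], right=1.0)


def empirical_cdf(distances, grid_step: float = 0.1,
                  grid_max: float | None = None) -> EmpiricalCDF:
    """Empirical CDF of a distance sample on a 0-anchored uniform grid."""
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("cannot build a CDF from an empty sample")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    top = grid_max if grid_max is not None else float(d.max())
    n_pts = int(math.ceil(top / grid_step - 1e-9)) + 1
    grid = np.arange(n_pts + 1) * grid_step
    ds = np.sort(d)
    vals = np.searchsorted(ds, grid + grid_step * 1e-9, side="right") / d.size
    return EmpiricalCDF(grid=grid, values=vals, n_observations=d.size, sample=ds)


@dataclass
class CdfSummary:
    """Cross-cell summary of per-cell distance CDFs on a common grid."""

    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    median: np.ndarray
    mad: np.ndarray
    global_cdf: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        for name in ("mean", "median", "global_cdf"):
            v = getattr(self, name)
            if np.any(np.diff(v) < -1e-9):
                raise ValueError(f"{name} summary CDF must be nondecreasing")
        if np.any(self.sd < 0) or np.any(self.mad < 0):
            raise ValueError("dispersion bands must be nonnegative")


def summarize_cdfs(per_cell: list[EmpiricalCDF]) -> CdfSummary:
    """Pointwise mean ± SD and median ± MAD across cells, plus pooled CDF.

    CDFs on differing grids are re-gridded by linear interpolation onto the
    finest-step, longest common grid (with a warning).  The global CDF
    pools raw distances when the per-cell samples were retained, else it
    falls back to the observation-weighted mean.
    """
    if not per_cell:
        raise ValueError("need at least one cell")
    steps = {round(c.grid_step, 12) for c in per_cell if c.grid.size > 1}
    step = min(steps) if steps else 0.1
    top = max(float(c.grid[-1]) for c in per_cell)
    if len(steps) > 1:
        warnings.warn("per-cell CDF grids differ; re-gridding by interpolation")
    grid = np.arange(int(round(top / step)) + 1) * step
    stack = np.stack([c.evaluate(grid) for c in per_cell])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(per_cell) > 1 else np.zeros_like(mean)
    med = np.median(stack, axis=0)
    mad = np.median(np.abs(stack - med), axis=0)
    samples = [c.sample for c in per_cell]
    if all(s is not None for s in samples):
        pooled = np.concatenate(samples)
        glob = empirical_cdf(pooled, grid_step=step, grid_max=float(grid[-1])).values
        glob = glob[: grid.size]
    else:
        weights = np.array([c.n_observations for c in per_cell], dtype=float)
        glob = (stack * weights[:, None]).sum(axis=0) / weights.sum()
    return CdfSummary(grid=grid, mean=mean, sd=sd, median=med, mad=mad,
                      global_cdf=glob, n_cells=len(per_cell))


def reference_cdfs(dmap, partition, grid_step: float = 0.1):
    """Reference CDFs of the distance map itself.

    Returns ``(cytosol_cdf, periphery_cdf)``: the distance distribution of
    all cytosolic voxels (what a uniformly distributed species would show)
    and of the periphery shell voxels (the outer envelope any intracellular
    signal can reach).
    """
    cyt = dmap.values[partition.cytosol]
    per = dmap.values[partition.periphery]
    if cyt.size == 0 or per.size == 0:
        raise ValueError("empty cytosol or periphery mask")
    top = float(max(cyt.max(), per.max()))
    return (
        empirical_cdf(cyt, grid_step=grid_step, grid_max=top),
        empirical_cdf(per, grid_step=grid_step, grid_max=top),
    )


def d50(cdf: EmpiricalCDF) -> float:
    """Smallest grid distance at which the CDF reaches 0.5.

    Grid-crossing convention (no interpolation) for bit-reproducibility.
    """
    if cdf.n_observations < 1:
        raise ValueError("CDF built from no observations")
    idx = np.searchsorted(cdf.values, 0.5 - 1e-12, side="left")
    idx = min(idx, cdf.grid.size - 1)
    return float(cdf.grid[idx])


@dataclass(frozen=True)
class TestResult:
    """A two-sample test outcome with multiple-comparison bookkeeping."""

    statistic: float
    p_value: float
    p_adjusted: float
    test: str
    comparison: str = ""
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 and 0 <= self.p_adjusted <= 1):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted + 1e-15 < self.p_value:
            raise ValueError("adjusted p cannot be smaller than raw p")

    @property
    def significant(self) -> bool:
        return self.p_adjusted < self.alpha


def ks_two_sample(dist_a, dist_b, comparison: str = "") -> TestResult:
    """Two-sample Kolmogorov–Smirnov test on pooled per-punctum distances.

    Exact p-value for small samples, asymptotic otherwise (scipy's 'auto'
    policy).
    """
    a = np.asarray(dist_a, dtype=float).ravel()
    b = np.asarray(dist_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("KS test needs at least two observations per sample")
    res = scipy.stats.ks_2samp(a, b, method="auto")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      p_adjusted=float(res.pvalue), test="ks_two_sample",
                      comparison=comparison)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Midranks handle ties; p is the fraction of the C(n+m, n) assignments
    whose rank sum deviates from its null mean at least as much as the
    observed one.
    """
    combined = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(combined)
    n, m = a.size, b.size
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    dev = abs(w_obs - mu)
    count = total = 0
    for subset in combinations(range(n + m), n):
        w = ranks[list(subset)].sum()
        total += 1
        if abs(w - mu) >= dev - 1e-9:
            count += 1
    return count / total


def wilcoxon_rank_sum(group_a, group_b, comparison: str = "") -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration of all rank assignments when n + m <= 12 (ties
    included); otherwise the normal approximation with tie correction.
    The reported statistic is the Mann–Whitney U of the first group.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = scipy.stats.rankdata(np.concatenate([a, b]))
    u_stat = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    if a.size + b.size <= 12:
        p = _exact_rank_sum_p(a, b)
        name = "wilcoxon_rank_sum_exact"
    else:
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic")
        p = float(res.pvalue)
        name = "wilcoxon_rank_sum_normal"
    return TestResult(statistic=u_stat, p_value=p, p_adjusted=p, test=name,
                      comparison=comparison)


def bonferroni(results: list[TestResult], m: int | None = None) -> list[TestResult]:
    """Bonferroni-adjust a family of test results: p_adj = min(1, m * p)."""
    if m is None:
        m = len(results)
    if m < len(results):
        raise ValueError(f"m={m} is smaller than the {len(results)} comparisons supplied")
    if m < 1:
        raise ValueError("m must be >= 1")
    return [replace(r, p_adjusted=min(1.0, m * r.p_value)) for r in results]


@dataclass
class ConcentrationProfile:
    """Signal concentration (% volume occupied) per nuclear-distance bin.

    ``percent`` is NaN for bins that contain no cytosolic voxels; such
    bins are flagged empty and excluded from :attr:`nonempty`.
    """

    bin_edges: np.ndarray
    percent: np.ndarray
    voxel_counts: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_edges.size != self.percent.size + 1:
            raise ValueError("need one more edge than bins")
        finite = self.percent[np.isfinite(self.percent)]
        if np.any((finite < 0) | (finite > 100)):
            raise ValueError("percentages must lie in [0, 100]")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def nonempty(self) -> tuple[np.ndarray, np.ndarray]:
        ok = self.voxel_counts > 0
        return self.bin_centers[ok], self.percent[ok]


def concentration_profile(signal_mask: np.ndarray, dmap, cytosol_mask: np.ndarray,
                          bin_width: float = 2.0) -> ConcentrationProfile:
    """% volume occupied by signal per distance-from-nucleus bin (cytosol only)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    dist = dmap.values[cytosol_mask]
    if dist.size == 0:
        raise ValueError("empty cytosol")
    sig = signal_mask[cytosol_mask]
    n_bins = int(math.ceil(dist.max() / bin_width)) or 1
    edges = np.arange(n_bins + 1) * bin_width
    which = np.minimum((dist / bin_width).astype(int), n_bins - 1)
    tot = np.bincount(which, minlength=n_bins)
    hit = np.bincount(which, weights=sig.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(tot > 0, 100.0 * hit / np.maximum(tot, 1), np.nan)
    return ConcentrationProfile(bin_edges=edges, percent=pct, voxel_counts=tot)


def ribosome_fraction(total_density: float, assoc_density: float) -> tuple[float, float]:
    """Fold difference and ribosome-associated percentage of two densities.

    ``fold = total / associated`` and ``percent = 100 * associated / total``
    — e.g. a 12.5-fold lower ribosome-associated density means 8% of the
    transcripts are ribosome-associated at any given time.
    """
    if total_density <= 0 or assoc_density <= 0:
        raise ValueError("densities must be positive")
    fold = total_density / assoc_density
    return fold, 100.0 * assoc_density / total_density
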