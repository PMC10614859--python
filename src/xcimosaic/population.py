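"""Population XCI-ratio distributions and embryonic cell-count inference.

XCI is a binomial coin-flip across the ``n_cells`` epiblast cells present
when inactivation is fixed, so the population variance of XCI ratios is
``p(1-p)/n_cells = 0.25/n_cells`` at fair choice.  The unfolded population
distribution is therefore modeled as Normal(0.5, 0.25/n_cells), a
continuous approximation to Binomial(n_cells, 0.5)/n_cells, and
``n_cells`` is recovered by matching model and empirical CDFs over the
distribution *tails* (ratios <= 0.40 or >= 0.60): folded estimates between
0.5 and 0.6 carry the most estimation uncertainty, so the central band is
left out of the fit.

Confidence intervals come from resampling the folded per-sample estimates
(the actual observations) with replacement and refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

GRID_STEP = 0.005
DEFAULT_GRID = (2, 200)
MIN_RECOMMENDED = 30


@dataclass
class PopulationDistribution:
    """A species' unfolded XCI-ratio distribution.

    ``values`` holds the mirror-unfolded ratios (each folded estimate f
    contributes f and 1-f with weight 1/2, so the mean is exactly 0.5);
    ``folded`` keeps the pre-mirroring estimates for bootstrap resampling;
    ``n_samples`` is the pre-mirroring sample count.
    """

    species: str
    values: np.ndarray
    folded: np.ndarray
    n_samples: int


@dataclass
class CellCountEstimate:
    n_cells: int
    sse: float
    fit_error: float
    ci95: tuple[int, int] | None = None
    n_bootstrap: int = 0


def unfold(folded_estimates, species: str = "") -> PopulationDistribution:
    """Mirror-unfold folded per-sample estimates into a population distribution.

    Folding discards the side of the skew, so each folded value f is given
    back both possible sides {f, 1-f} at half weight.  This adds no
    randomness, preserves the folded information exactly, and makes the
    distribution symmetric about 0.5 by construction.
    """
    folded = np.asarray(folded_estimates, dtype=float)
    folded = folded[np.isfinite(folded)]
    if folded.size == 0:
        raise ValueError("cannot unfold an empty set of estimates")
    if np.any((folded < 0.5) | (folded > 1.0)):
        raise ValueError("folded estimates must lie in [0.5, 1]")
    values = np.concatenate([folded, 1.0 - folded])
    return PopulationDistribution(species=species, values=values, folded=folded, n_samples=folded.size)


def model_variance(n_cells: int) -> float:
    """Variance of the XCI-ratio distribution for ``n_cells`` cells: 0.25/n."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return 0.25 / n_cells


def cell_divisions(n_cells: float) -> float:
    """Cell count on the log2 scale (number of doublings from one cell)."""
    return float(np.log2(n_cells))


@lru_cache(maxsize=8)
def _evaluation_grid(tail_lo: float, tail_hi: float) -> np.ndarray:
    lo = np.arange(0.0, tail_lo + GRID_STEP / 2, GRID_STEP)
    hi = np.arange(tail_hi, 1.0 + GRID_STEP / 2, GRID_STEP)
    return np.concatenate([lo, hi])


@lru_cache(maxsize=8)
def _model_cdfs(tail_lo: float, tail_hi: float, n_lo: int, n_hi: int) -> np.ndarray:
    grid = _evaluation_grid(tail_lo, tail_hi)
    ns = np.arange(n_lo, n_hi + 1)
    sd = np.sqrt(0.25 / ns)
    return stats.norm.cdf(grid[None, :], loc=0.5, scale=sd[:, None])


def _ecdf(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(values), grid, side="right") / values.size


def fit_cell_count(
    dist: PopulationDistribution | np.ndarray,
    tail_lo: float = 0.40,
    tail_hi: float = 0.60,
    grid: tuple[int, int] = DEFAULT_GRID,
) -> CellCountEstimate:
    """Grid-search the cell count minimizing tail CDF error.

    For each candidate n in ``grid`` the sum of squared differences
    between the Normal(0.5, 0.25/n) CDF and the empirical CDF is computed
    on the fixed ratio grid {0, 0.005, ..., tail_lo} ∪ {tail_hi, ..., 1};
    the argmin is returned (ties break to the smaller, more conservative
    n).  ``fit_error`` is the mean absolute CDF deviation at the optimum
    over the same grid.
    """
    values = dist.values if isinstance(dist, PopulationDistribution) else np.asarray(dist, float)
    if values.size == 0:
        raise ValueError("empty distribution")
    if values.size < MIN_RECOMMENDED:
        logger.warning("only %d unfolded values; cell-count fit will be unstable", values.size)
    eval_grid = _evaluation_grid(tail_lo, tail_hi)
    models = _model_cdfs(tail_lo, tail_hi, grid[0], grid[1])
    ecdf = _ecdf(values, eval_grid)
    diffs = models - ecdf[None, :]
    sse = np.sum(diffs**2, axis=1)
    k = int(np.argmin(sse))  # first minimum -> smallest n on ties
    return CellCountEstimate(
        n_cells=int(grid[0] + k),
        sse=float(sse[k]),
        fit_error=float(np.mean(np.abs(diffs[k]))),
    )


def bootstrap_ci(
    dist: PopulationDistribution,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    tail_lo: float = 0.40,
    tail_hi: float = 0.60,
    grid: tuple[int, int] = DEFAULT_GRID,
) -> tuple[int, int]:
    """Percentile bootstrap CI for the cell count.

    Resamples the folded per-sample estimates (pre-mirroring) with
    replacement at the original sample size, re-unfolds and refits; the
    interval leaves ``(1 - level)/2`` of the bootstrap distribution
    outside each end.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folded = dist.folded
    n = folded.size
    eval_grid = _evaluation_grid(tail_lo, tail_hi)
    models = _model_cdfs(tail_lo, tail_hi, grid[0], grid[1])
    model_sq = np.sum(models**2, axis=1)

    draws = rng.integers(0, n, size=(n_boot, n))
    resampled = folded[draws]
    unfolded = np.concatenate([resampled, 1.0 - resampled], axis=1)
    unfolded.sort(axis=1)
    ecdfs = np.empty((n_boot, eval_grid.size))
    for b in range(n_boot):
        ecdfs[b] = np.searchsorted(unfolded[b], eval_grid, side="right") / (2 * n)
    # sse[b, k] = ||m_k||^2 - 2 m_k . e_b + ||e_b||^2; constant ||e_b||^2 dropped
    scores = model_sq[None, :] - 2.0 * ecdfs @ models.T
    hats = grid[0] + np.argmin(scores, axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(hats, [100 * alpha, 100 * (1 - alpha)], method="nearest")
    return int(lo), int(hi)


def estimate_population(
    folded_estimates,
    species: str = "",
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    tail_lo: float = 0.40,
    tail_hi: float = 0.60,
    grid: tuple[int, int] = DEFAULT_GRID,
) -> tuple[PopulationDistribution, CellCountEstimate]:
    """Unfold, fit, and bootstrap in one call."""
    dist = unfold(folded_estimates, species=species)
    est = fit_cell_count(dist, tail_lo=tail_lo, tail_hi=tail_hi, grid=grid)
    if n_boot > 0:
        est.ci95 = bootstrap_ci(dist, n_boot=n_boot, seed=seed, tail_lo=tail_lo, tail_hi=tail_hi, grid=grid)
        est.n_bootstrap = n_boot
    return dist, est
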