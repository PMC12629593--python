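"""Extreme-value ("first firefly to flash") group interburst statistics.

If each of N fireflies independently waits a time drawn from a density
b(t) before flashing, and any flash immediately triggers the whole group,
the collective interburst interval is the *minimum* of N draws.  Writing
gamma(t) = ∫_t^∞ b for the single-firefly survival function, the group
density is

    P_N(t) = N * gamma(t)^(N-1) * b(t),

whose moments are <T_N^m> = m ∫ gamma^N(t) t^(m-1) dt.  All moments and
the variance decrease monotonically in N, the left-most mode drifts toward
the refractory floor t_min, and P_N collapses onto a delta at t_min as
N → ∞ — emergent periodicity at the fastest interval any individual can
produce.  A brute-force min-of-N Monte-Carlo oracle is included for
validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import IBIDensity, IBISamples, sample_ibi

__all__ = [
    "SurvivalCurve",
    "GroupIBIDensity",
    "survival_curve",
    "group_cdf",
    "group_density",
    "group_density_hetero",
    "group_moment",
    "group_variance",
    "std_vs_N",
    "leftmost_mode",
    "min_of_n_oracle",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """gamma(t): probability an isolated firefly waits longer than t."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if np.any(np.diff(vals) > 1e-12):
            raise ValueError("survival curve must be non-increasing")


@dataclass(frozen=True)
class GroupIBIDensity(IBIDensity):
    """P_N(T_b): the group ("first to flash") interburst density."""

    N: int = 1

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.N < 1:
            raise ValueError("N must be >= 1")


def survival_curve(b: IBIDensity) -> SurvivalCurve:
    """gamma(t) = ∫_t^∞ b by reverse cumulative trapezoid on b's grid."""
    cdf = b.cdf_grid()
    gamma = np.clip(1.0 - cdf, 0.0, 1.0)
    return SurvivalCurve(times=b.times, values=gamma)


def _gamma_pow(gamma: np.ndarray, k: int) -> np.ndarray:
    # gamma ** k with exact handling of gamma == 0 and k == 0; harmless
    # underflow to 0 for large k is the correct limit.
    if k == 0:
        return np.ones_like(gamma)
    with np.errstate(under="ignore"):
        return np.power(gamma, k)


def group_density(b: IBIDensity, N: int) -> GroupIBIDensity:
    """P_N(t) = N gamma^(N-1) b(t), renormalized on the grid.

    Renormalization corrects the trapezoid discretization error so that
    the exact-in-the-continuum identity keeps unit probability; N = 1
    returns b itself (up to that tolerance).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    gamma = survival_curve(b).values
    dens = N * _gamma_pow(gamma, N - 1) * b.density
    return GroupIBIDensity.from_values(b.times, dens, t_min=b.t_min,
                                       t_max=b.t_max, grid_step=b.grid_step, N=N)


def group_density_hetero(bs: list[IBIDensity]) -> GroupIBIDensity:
    """First-to-flash density for fireflies with individual densities b_i.

    P_N(t) = Σ_i b_i(t) Π_{j≠i} gamma_j(t).  Densities must share the grid
    step; shorter grids are zero-padded to the longest.  Reduces to
    ``group_density`` when all inputs are identical.
    """
    if not bs:
        raise ValueError("need at least one density")
    step = bs[0].grid_step
    if any(abs(b.grid_step - step) > 1e-12 for b in bs):
        raise ValueError("mismatched grid steps")
    n_grid = max(b.times.size for b in bs)
    times = np.arange(n_grid) * step

    dens_mat = np.zeros((len(bs), n_grid))
    gam_mat = np.zeros((len(bs), n_grid))
    for i, b in enumerate(bs):
        dens_mat[i, : b.times.size] = b.density
        gam_mat[i, : b.times.size] = survival_curve(b).values
        # beyond a component's grid its survival stays 0 (already flashed)
    total = np.zeros(n_grid)
    for i in range(len(bs)):
        prod = np.ones(n_grid)
        for j in range(len(bs)):
            if j != i:
                prod *= gam_mat[j]
        total += dens_mat[i] * prod
    t_min = min(b.t_min for b in bs)
    t_max = max(b.t_max for b in bs)
    return GroupIBIDensity.from_values(times, total, t_min=t_min, t_max=t_max,
                                       grid_step=step, N=len(bs))


def group_cdf(b: IBIDensity, N: int):
    """Exact CDF of the min of N draws from b: t ↦ 1 - (1 - F_b(t))^N.

    Consistent with ``sample_ibi``'s piecewise-linear CDF, so it is the
    right reference when testing Monte-Carlo minima against the theory.
    """
    if N < 1:
        raise ValueError("N must be >= 1")

    def cdf(t):
        return 1.0 - (1.0 - b.cdf(t)) ** N

    return cdf


def group_moment(b: IBIDensity, N: int, m: int) -> float:
    """m-th raw moment of the group interval: m ∫ gamma^N(t) t^(m-1) dt."""
    if m < 0:
        raise ValueError("moment order must be >= 0")
    if m == 0:
        return 1.0
    if N < 1:
        raise ValueError("N must be >= 1")
    gamma_n = _gamma_pow(survival_curve(b).values, N)
    return float(m * np.trapezoid(gamma_n * b.times ** (m - 1), b.times))


def group_variance(b: IBIDensity, N: int) -> float:
    """Variance of the group interval; monotone non-increasing in N."""
    m1 = group_moment(b, N, 1)
    m2 = group_moment(b, N, 2)
    return max(m2 - m1 * m1, 0.0)


def std_vs_N(b: IBIDensity, Ns: list[int]) -> pd.DataFrame:
    """Standard deviation of the group interval for each swarm size."""
    if len(Ns) == 0:
        raise ValueError("Ns must be non-empty")
    stds = [float(np.sqrt(group_variance(b, int(N)))) for N in Ns]
    return pd.DataFrame({"N": list(Ns), "std": stds})


def leftmost_mode(p: IBIDensity) -> float:
    """Time of the left-most local maximum of the gridded density.

    The first grid point whose value exceeds its left neighbour (zero below
    the support, so a peak at the support edge counts) and is >= its right
    neighbour; plateaus resolve to their smallest time.
    """
    d = p.density
    if not np.any(d > 0):
        raise ValueError("flat-zero density has no mode")
    left = np.concatenate(([-np.inf], d[:-1]))
    right = np.concatenate((d[1:], [-np.inf]))
    idx = np.nonzero((d > 0) & (d > left) & (d >= right))[0]
    return float(p.times[idx[0]])


def min_of_n_oracle(b: IBIDensity, N: int, n_samples: int, seed: int) -> IBISamples:
    """Brute-force oracle: each sample is the min of N independent draws."""
    if N < 1 or n_samples < 1:
        raise ValueError("N and n_samples must be >= 1")
    draws = sample_ibi(b, N * n_samples, seed).reshape(n_samples, N)
    return IBISamples(values=draws.min(axis=1), label=f"min-of-{N} oracle")
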