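"""Coupling-strength inference by Kolmogorov–Smirnov minimization.

The simulator's one free parameter is the coupling strength beta.  To fit
it, simulated group interburst-interval distributions are compared with a
reference distribution (experimental or simulated) via the two-sample KS
statistic D = sup |ECDF_a - ECDF_b|, on a (beta, N) grid; the best beta per
swarm size N is the argmin of D (ties toward smaller beta).  Replicate
simulations are pooled into a single sample before the test, after
discarding burn-in bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bursts import DEFAULT_GAP_S, detect_bursts, interburst_intervals, IBISampleSet
from .distributions import FlashLengthDensity, IBIDensity
from .simulate import FlashSeries, SwarmConfig, run_replicates

__all__ = [
    "DEFAULT_BETA_GRID",
    "DEFAULT_N_TRIALS",
    "SweepResult",
    "ks_two_sample",
    "pooled_burst_intervals",
    "beta_sweep",
    "select_best_beta",
]

#: beta in [0, 1] in steps of 0.02.
DEFAULT_BETA_GRID = np.round(np.arange(0, 51) * 0.02, 10)
DEFAULT_N_TRIALS = 10


@dataclass(frozen=True)
class SweepResult:
    """KS surface over (beta, N); D[i, j] for beta_grid[i], N_list[j]."""

    beta_grid: np.ndarray
    N_list: list[int]
    D: np.ndarray
    p: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        if self.D.shape != (len(self.beta_grid), len(self.N_list)):
            raise ValueError("D shape must be (len(beta_grid), len(N_list))")
        if np.any((self.D < 0) | (self.D > 1)) or np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("D and p must lie in [0, 1]")

    @property
    def best_beta(self) -> dict[int, float]:
        return select_best_beta(self)

    def to_frame(self) -> pd.DataFrame:
        rows = [(N, float(beta), float(self.D[i, j]), float(self.p[i, j]))
                for j, N in enumerate(self.N_list)
                for i, beta in enumerate(self.beta_grid)]
        return pd.DataFrame(rows, columns=["N", "beta", "ks_D", "ks_p"])


def ks_two_sample(a: IBISampleSet, b: IBISampleSet) -> tuple[float, float]:
    """Two-sided two-sample KS statistic and asymptotic p-value."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample set")
    res = stats.ks_2samp(a.intervals, b.intervals, method="asymp")
    return float(res.statistic), float(res.pvalue)


def pooled_burst_intervals(series: list[FlashSeries],
                           gap: float = DEFAULT_GAP_S,
                           burn_in_bursts: int = 0) -> IBISampleSet:
    """Burst-based IBIs pooled over trials, after per-trial burn-in."""
    pooled: list[np.ndarray] = []
    for fs in series:
        train = detect_bursts(fs, gap=gap)
        starts = train.burst_start_times[burn_in_bursts:]
        if starts.size >= 2:
            pooled.append(np.diff(starts))
    if not pooled:
        raise ValueError("no interburst intervals after burn-in")
    return IBISampleSet(intervals=np.concatenate(pooled),
                        definition="burst_first_to_first")


def beta_sweep(beta_grid: np.ndarray,
               N_list: list[int],
               reference: dict[int, IBISampleSet],
               config: SwarmConfig,
               b: IBIDensity,
               d: FlashLengthDensity,
               n_trials: int = DEFAULT_N_TRIALS,
               gap: float = DEFAULT_GAP_S) -> SweepResult:
    """KS statistic of simulation vs reference on every (beta, N) cell.

    ``reference`` maps each N to its reference interval sample.  Each cell
    pools burst-based IBIs (after burn-in) from ``n_trials`` replicate
    simulations; cell seeds are offsets of ``config.seed`` so the whole
    sweep is deterministic.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if beta_grid.size == 0 or len(N_list) == 0:
        raise ValueError("empty sweep grid")
    missing = [N for N in N_list if N not in reference]
    if missing:
        raise ValueError(f"no reference sample for N = {missing}")
    D = np.zeros((beta_grid.size, len(N_list)))
    p = np.zeros_like(D)
    for j, N in enumerate(N_list):
        for i, beta in enumerate(beta_grid):
            cell_seed = config.seed + (j * beta_grid.size + i) * n_trials
            cell_cfg = replace(config, N=int(N), beta=float(beta),
                               seed=int(cell_seed), adjacency=None)
            try:
                series = run_replicates(cell_cfg, b, d, n_trials)
                sim = pooled_burst_intervals(
                    series, gap=gap, burn_in_bursts=config.burn_in_bursts)
                D[i, j], p[i, j] = ks_two_sample(sim, reference[N])
            except ValueError as err:
                raise ValueError(
                    f"sweep cell failed at beta={beta}, N={N}: {err}") from err
    return SweepResult(beta_grid=beta_grid, N_list=list(N_list), D=D, p=p,
                       n_trials=n_trials)


def select_best_beta(result: SweepResult) -> dict[int, float]:
    """argmin_beta D per N; np.argmin's first-hit rule breaks ties low."""
    return {int(N): float(result.beta_grid[int(np.argmin(result.D[:, j]))])
            for j, N in enumerate(result.N_list)}
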