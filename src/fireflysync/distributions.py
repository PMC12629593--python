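"""Interburst-interval (IBI) and flash-length densities.

An isolated *Photinus carolinus* firefly emits flash bursts separated by
waiting times drawn from a broad, heavy-right-tailed distribution ``b(t)``
with a hard physiological minimum (refractory floor) ``t_min``.  This module
represents such densities on a uniform time grid, constructs them from raw
interval samples via a histogram-plus-cubic-spline "envelope" protocol,
samples from them, and synthesises parametric stand-ins (shifted exponential
/ shifted lognormal) for testing and simulation without field data.

All times are in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline

__all__ = [
    "CLEAN_CUTOFF_S",
    "DEFAULT_N_BINS",
    "DEFAULT_GRID_STEP_S",
    "IBISamples",
    "IBIDensity",
    "FlashLengthDensity",
    "ParametricIBIModel",
    "clean_samples",
    "envelope_bin_edges",
    "build_envelope",
    "sample_ibi",
    "parametric_density",
    "sample_parametric",
    "default_ibi_model",
    "default_flash_length_density",
]

#: Intervals below this are within-burst ("interflash") gaps, not IBIs.
CLEAN_CUTOFF_S = 2.0
#: Histogram bins used by the envelope protocol.
DEFAULT_N_BINS = 50
#: Uniform grid resolution for all densities.
DEFAULT_GRID_STEP_S = 0.1

_NORM_TOL = 1e-6


@dataclass(frozen=True)
class IBISamples:
    """A cleaned list of interburst intervals (seconds)."""

    values: np.ndarray
    label: str = ""
    n_removed: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.size == 0:
            raise ValueError("IBISamples must be non-empty")
        if not np.all(vals > 0):
            raise ValueError("IBI samples must be strictly positive")

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class IBIDensity:
    """A normalized waiting-time density b(t) on a uniform grid.

    The grid runs from 0 to (approximately) ``t_max`` in steps of
    ``grid_step``; the density is exactly zero below the refractory floor
    ``t_min`` and integrates to 1 (trapezoid rule on its own grid).
    The density is treated as piecewise linear between grid points for all
    integrals and for inverse-CDF sampling.
    """

    times: np.ndarray
    density: np.ndarray
    t_min: float
    t_max: float
    grid_step: float = DEFAULT_GRID_STEP_S

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "density", dens)
        if times.shape != dens.shape or times.ndim != 1:
            raise ValueError("times and density must be matching 1-d arrays")
        if not self.t_min < self.t_max:
            raise ValueError(f"need t_min < t_max, got [{self.t_min}, {self.t_max}]")
        if np.any(dens < 0):
            raise ValueError("density must be non-negative")
        if np.any(dens[times < self.t_min] != 0):
            raise ValueError("density must vanish below t_min")
        total = self.integral()
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"density integrates to {total!r}, expected 1")

    @classmethod
    def from_values(
        cls,
        times: np.ndarray,
        density: np.ndarray,
        t_min: float,
        t_max: float,
        grid_step: float = DEFAULT_GRID_STEP_S,
        **kwargs,
    ) -> "IBIDensity":
        """Clip negatives, zero outside the support, renormalize, construct."""
        times = np.asarray(times, dtype=float)
        dens = np.clip(np.asarray(density, dtype=float), 0.0, None)
        dens = np.where((times < t_min) | (times > t_max), 0.0, dens)
        total = np.trapezoid(dens, times)
        if total <= 0:
            raise ValueError("density is identically zero on its support")
        return cls(times=times, density=dens / total, t_min=t_min, t_max=t_max,
                   grid_step=grid_step, **kwargs)

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.times))

    def mean(self) -> float:
        return float(np.trapezoid(self.times * self.density, self.times))

    def var(self) -> float:
        m1 = self.mean()
        m2 = float(np.trapezoid(self.times**2 * self.density, self.times))
        return max(m2 - m1 * m1, 0.0)

    def std(self) -> float:
        return math.sqrt(self.var())

    def cdf_grid(self) -> np.ndarray:
        """Cumulative distribution at the grid points (ends at exactly 1).

        The density has a jump at the refractory floor: it is identically
        zero below t_min, not linearly rising from the last zero grid
        point.  Plain trapezoid would therefore leak mass into the cell
        straddling t_min (badly amplified in gamma^N for large N), so that
        cell's contribution is restricted to [t_min, right edge].
        """
        t, d = self.times, self.density
        cell = 0.5 * (d[:-1] + d[1:]) * np.diff(t)
        below = t[:-1] < self.t_min
        strad = below & (t[1:] > self.t_min)
        cell[below] = 0.0
        cell[strad] = (t[1:][strad] - self.t_min) * d[1:][strad]
        c = np.concatenate(([0.0], np.cumsum(cell)))
        return c / c[-1]

    def cdf(self, t) -> np.ndarray:
        """Piecewise-linear CDF evaluated at arbitrary times."""
        return np.interp(t, self.times, self.cdf_grid())


@dataclass(frozen=True)
class FlashLengthDensity(IBIDensity):
    """Discharge (flash) duration density T_d; support strictly positive."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.t_min <= 0:
            raise ValueError("flash lengths require t_min > 0")


@dataclass(frozen=True)
class ParametricIBIModel:
    """Synthetic IBI model: a hard refractory floor t0 plus a positive tail.

    family ``shifted_exponential``: t = t0 + Exp(rate).
    family ``shifted_lognormal``: t = t0 + LogNormal(mu, sigma) with
    ``median`` the median of the *shifted* variable, i.e. e^mu = median - t0.
    ``t_max`` truncates the density grid; None means effectively untruncated
    (the grid extends to the 1 - 1e-6 quantile).
    """

    family: str
    t0: float
    rate: float | None = None
    median: float | None = None
    sigma: float | None = None
    t_max: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("shifted_exponential", "shifted_lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.t0 < 0 or not np.isfinite(self.t0):
            raise ValueError("t0 must be finite and >= 0")
        if self.family == "shifted_exponential":
            if self.rate is None or self.rate <= 0 or not np.isfinite(self.rate):
                raise ValueError("shifted_exponential needs rate > 0")
        else:
            if self.sigma is None or self.sigma <= 0 or not np.isfinite(self.sigma):
                raise ValueError("shifted_lognormal needs sigma > 0")
            if self.median is None or self.median <= self.t0:
                raise ValueError("shifted_lognormal needs median > t0")
        if self.t_max is not None and self.t_max <= self.t0:
            raise ValueError("t_max must exceed t0")

    def frozen(self):
        """The scipy frozen distribution of the (untruncated) variable."""
        if self.family == "shifted_exponential":
            return stats.expon(loc=self.t0, scale=1.0 / self.rate)
        return stats.lognorm(s=self.sigma, loc=self.t0, scale=self.median - self.t0)

    def upper(self) -> float:
        """Effective grid upper bound."""
        if self.t_max is not None:
            return float(self.t_max)
        return float(self.frozen().ppf(1.0 - 1e-6))


def clean_samples(
    raw: Sequence[float], cutoff: float = CLEAN_CUTOFF_S, label: str = ""
) -> IBISamples:
    """Drop sub-cutoff intervals (within-burst interflash gaps) from raw IBIs.

    Order is preserved; the number of removed values is recorded on the
    result.  Raises if nothing survives.
    """
    vals = np.asarray(list(raw), dtype=float)
    if vals.size == 0:
        raise ValueError("no input samples")
    kept = vals[vals >= cutoff]
    if kept.size == 0:
        raise ValueError(f"all {vals.size} samples removed by cutoff {cutoff} s: "
                         "empty after cleaning")
    return IBISamples(values=kept, label=label, n_removed=int(vals.size - kept.size))


def envelope_bin_edges(samples: IBISamples, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Uniform histogram bin edges over [min, max] of the samples."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if samples.min == samples.max:
        raise ValueError("degenerate samples: min == max")
    return np.linspace(samples.min, samples.max, n_bins + 1)


def build_envelope(
    samples: IBISamples,
    n_bins: int = DEFAULT_N_BINS,
    grid_step: float = DEFAULT_GRID_STEP_S,
) -> IBIDensity:
    """Histogram → cubic-spline "envelope" density for cleaned IBI samples.

    A density histogram with ``n_bins`` uniform bins on [min, max] is
    splined (natural cubic through the bin centers), evaluated on the
    ``grid_step`` grid, zero-padded on [0, min), clipped at zero where the
    spline undershoots, and renormalized to unit area.
    """
    edges = envelope_bin_edges(samples, n_bins)
    heights, _ = np.histogram(samples.values, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    spline = CubicSpline(centers, heights, bc_type="natural")

    t_min, t_max = samples.min, samples.max
    n = int(math.floor(t_max / grid_step + 1e-9))
    times = np.arange(n + 1) * grid_step
    dens = np.where(times >= t_min, spline(times), 0.0)
    return IBIDensity.from_values(times, dens, t_min=t_min, t_max=t_max,
                                  grid_step=grid_step)


def sample_ibi(density: IBIDensity, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` waiting times by inverse CDF on the piecewise-linear CDF.

    Deterministic given ``seed``; every draw lies in [t_min, t_max].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    draws = np.interp(u, density.cdf_grid(), density.times)
    return np.clip(draws, density.t_min, density.t_max)


def parametric_density(
    model: ParametricIBIModel,
    grid_step: float = DEFAULT_GRID_STEP_S,
    cls: type = IBIDensity,
) -> IBIDensity:
    """Grid, truncate and renormalize a parametric IBI model."""
    upper = model.upper()
    n = int(math.floor(upper / grid_step + 1e-9))
    times = np.arange(n + 1) * grid_step
    dens = model.frozen().pdf(times)
    return cls.from_values(times, dens, t_min=model.t0, t_max=upper,
                           grid_step=grid_step)


def sample_parametric(model: ParametricIBIModel, n: int, seed: int) -> np.ndarray:
    """Draw directly from the parametric model (truncated at t_max if set)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    frozen = model.frozen()
    hi = frozen.cdf(model.t_max) if model.t_max is not None else 1.0
    return frozen.ppf(rng.uniform(0.0, hi, size=n))


def default_ibi_model() -> ParametricIBIModel:
    """Canonical synthetic stand-in for a single firefly's IBI distribution.

    Heavy-right-tailed shifted lognormal with the refractory floor at
    5.672 s and support capped at 1400 s, matching the observed range of
    isolated-firefly interburst intervals (a few seconds to tens of
    minutes) with a median of 30 s.
    """
    return ParametricIBIModel(family="shifted_lognormal", t0=5.672,
                              median=30.0, sigma=1.0, t_max=1400.0)


def default_flash_length_density(grid_step: float = DEFAULT_GRID_STEP_S) -> FlashLengthDensity:
    """Stand-in discharge-duration density: flashes last on the order of 1 s.

    Synthetic shifted lognormal (t0 = 0.2 s, median 1.0 s, sigma 0.3); the
    published flash-length measurements are not bundled with this package.
    """
    model = ParametricIBIModel(family="shifted_lognormal", t0=0.2,
                               median=1.0, sigma=0.3, t_max=3.0)
    return parametric_density(model, grid_step=grid_step, cls=FlashLengthDensity)
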