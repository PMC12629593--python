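"""Delimited-text readers and writers plus flat run configuration.

Four file formats, all UTF-8 delimited text with one header line
(delimiter inferred from extension: ``.tsv`` → tab, otherwise comma):

* IBI samples      — header ``ibi_s``, one interval (s) per row;
* density          — header ``t_s,density``, one grid point per row;
* flash series     — header ``agent_id,t_start,t_end``, sorted by start;
* sweep table      — header ``N,beta,ks_D,ks_p``; best-beta summary
                     ``N,best_beta,min_D``.

Floats are written with 6 decimals, enough for lossless round trips at the
0.1 s grid / 0.009 s timestep resolution used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .bursts import IBISampleSet
from .distributions import (DEFAULT_GRID_STEP_S, IBIDensity, IBISamples)
from .fitting import SweepResult
from .simulate import FlashSeries

__all__ = [
    "read_samples", "write_samples",
    "read_density", "write_density",
    "read_flash_series", "write_flash_series",
    "write_sweep", "read_sweep", "write_best_beta",
    "write_summary",
    "RunConfig",
]

logger = logging.getLogger("fireflysync")

_FLOAT_FMT = "%.6f"


def _sep(path: Path) -> str:
    return "\t" if Path(path).suffix == ".tsv" else ","


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep(path))
    except Exception as err:
        raise ValueError(f"{path}: unreadable table ({err})") from err
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: expected header {','.join(columns)!r}, got "
            f"{','.join(map(str, df.columns))!r}")
    bad = df.index[df.apply(pd.to_numeric, errors="coerce").isna().any(axis=1)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric fields on line(s) {lines}")
    return df.apply(pd.to_numeric)


def read_samples(path) -> IBISamples:
    df = _read_table(path, ["ibi_s"])
    return IBISamples(values=df["ibi_s"].to_numpy(), label=str(path))


def write_samples(samples, path) -> None:
    vals = samples.values if isinstance(samples, IBISamples) else samples.intervals
    pd.DataFrame({"ibi_s": np.asarray(vals, dtype=float)}).to_csv(
        path, index=False, sep=_sep(Path(path)), float_format=_FLOAT_FMT)


def read_density(path, grid_step: float = DEFAULT_GRID_STEP_S) -> IBIDensity:
    """Read a gridded density; renormalizes (with a warning) if area != 1."""
    df = _read_table(path, ["t_s", "density"])
    times = df["t_s"].to_numpy()
    dens = df["density"].to_numpy()
    total = float(np.trapezoid(dens, times))
    if abs(total - 1.0) > 1e-6:
        logger.warning("%s: density integrates to %.6g, renormalizing", path, total)
    support = times[dens > 0]
    if support.size == 0:
        raise ValueError(f"{path}: density is identically zero")
    t_min = float(support.min())
    t_max = float(times.max())
    return IBIDensity.from_values(times, dens, t_min=t_min, t_max=t_max,
                                  grid_step=grid_step)


def write_density(density: IBIDensity, path) -> None:
    pd.DataFrame({"t_s": density.times, "density": density.density}).to_csv(
        path, index=False, sep=_sep(Path(path)), float_format=_FLOAT_FMT)


def read_flash_series(path) -> FlashSeries:
    df = _read_table(path, ["agent_id", "t_start", "t_end"])
    starts = df["t_start"].to_numpy()
    if np.any(np.diff(starts) < 0):
        logger.warning("%s: flash series not sorted by t_start; sorting", path)
    ends = df["t_end"].to_numpy()
    return FlashSeries(agent_id=df["agent_id"].to_numpy(np.int64),
                       t_start=starts, t_end=ends,
                       duration=float(ends.max()))


def write_flash_series(series: FlashSeries, path) -> None:
    df = series.to_frame()
    df["t_start"] = df["t_start"].map(lambda v: f"{v:.6f}")
    df["t_end"] = df["t_end"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False, sep=_sep(Path(path)))


def write_sweep(result: SweepResult, path) -> None:
    result.to_frame().to_csv(path, index=False, sep=_sep(Path(path)),
                             float_format=_FLOAT_FMT)


def read_sweep(path) -> pd.DataFrame:
    return _read_table(path, ["N", "beta", "ks_D", "ks_p"])


def write_best_beta(result: SweepResult, path) -> None:
    best = result.best_beta
    rows = [(N, best[N], float(result.D[:, j].min()))
            for j, N in enumerate(result.N_list)]
    pd.DataFrame(rows, columns=["N", "best_beta", "min_D"]).to_csv(
        path, index=False, sep=_sep(Path(path)), float_format=_FLOAT_FMT)


def write_summary(summary, path) -> None:
    """Write a bursts.Summary as `stat,value` rows."""
    pd.DataFrame({"stat": ["mode", "mean", "std"],
                  "value": [summary.mode, summary.mean, summary.std]}).to_csv(
        path, index=False, sep=_sep(Path(path)), float_format=_FLOAT_FMT)


@dataclass
class RunConfig:
    """Flat, serializable run configuration for the CLI.

    Serialized as ``key = value`` lines; CLI flags override file values.
    """

    N: int = 20
    beta: float = 0.0
    dt: float = 0.009
    n_steps: int = 200_000
    seed: int = 0
    burn_in_bursts: int = 5
    n_bins: int = 50
    grid_step: float = DEFAULT_GRID_STEP_S
    min_cutoff: float = 2.0
    gap: float = 2.0
    bin_width: float = 0.5
    n_trials: int = 10
    beta_grid: str = "0:1:0.02"
    N_list: str = "5,10,15,20"
    outdir: str = "."

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {ln}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"{path}: line {ln}: unknown key {key!r}")
            kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)

    def parse_beta_grid(self) -> np.ndarray:
        lo, hi, step = (float(x) for x in self.beta_grid.split(":"))
        n = int(round((hi - lo) / step))
        return np.round(lo + step * np.arange(n + 1), 10)

    def parse_N_list(self) -> list[int]:
        return [int(x) for x in self.N_list.split(",") if x.strip()]
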