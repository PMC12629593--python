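"""Stochastic pulse-coupled integrate-and-fire swarm simulator.

Each of N agents carries a voltage V ∈ [0, 1] and a binary state eps
(1 = charging/quiet, 0 = discharging/flashing).  Per agent the voltage
obeys

    dV_i/dt = eps_i / Ts_i  -  (1 - eps_i) / Td_i
              + eps_i * Σ_j (beta / N) * adj_ij * (1 - eps_j),

where Tb_i (start-to-start interval) and Td_i (flash length) are random
variables resampled from their input densities at every state switch and
Ts_i = Tb_i - Td_i is the charging time.  A charging agent is "pulled"
toward its flash threshold (V = 1) at an extra rate beta/N per flashing
neighbour; a flashing agent ignores its neighbours.  beta = 0 gives
independent renewal flashers; beta → ∞ recovers the idealized
first-to-flash theory where one flash instantly triggers the whole swarm.

The three-step update per timestep: (1) threshold crossings flip eps
(V ≥ 1: start flashing; V ≤ 0: stop and resample Tb, Td); (2) agents with
eps = 0 are flashing during the step; (3) Euler-forward voltage update
using a synchronous snapshot of eps, clamped to [0, 1].

The hot loop is compiled with numba; ``step`` is a plain-Python reference
implementation of one timestep used for inspection and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .distributions import FlashLengthDensity, IBIDensity

__all__ = [
    "DEFAULT_DT_S",
    "DEFAULT_N_STEPS",
    "SwarmConfig",
    "AgentState",
    "FlashSeries",
    "init_swarm",
    "step",
    "simulate",
    "run_replicates",
]

#: Timestep: 200000 steps span 30 min of real time, so dt = 1800 s / 200000.
DEFAULT_DT_S = 0.009
DEFAULT_N_STEPS = 200_000
_MAX_RESAMPLE_TRIES = 10_000


@dataclass(frozen=True)
class SwarmConfig:
    """Simulation parameters.

    ``adjacency`` is a binary N×N matrix with zero diagonal (a firefly does
    not stimulate itself); None means all-to-all.  The pairwise coupling is
    beta / N regardless of adjacency.  ``burn_in_bursts`` collective bursts
    are discarded by downstream analysis to remove initialization
    transients.
    """

    N: int
    beta: float
    dt: float = DEFAULT_DT_S
    n_steps: int = DEFAULT_N_STEPS
    seed: int = 0
    adjacency: np.ndarray | None = None
    burn_in_bursts: int = 5

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.dt <= 0 or self.n_steps < 1:
            raise ValueError("dt must be > 0 and n_steps >= 1")
        if self.adjacency is not None:
            adj = np.asarray(self.adjacency)
            if adj.shape != (self.N, self.N):
                raise ValueError("adjacency must be N x N")
            if not np.array_equal(adj, adj.T) or np.any(np.diag(adj) != 0):
                raise ValueError("adjacency must be symmetric with zero diagonal")
            if not np.all(np.isin(adj, (0, 1))):
                raise ValueError("adjacency must be binary")
            object.__setattr__(self, "adjacency", adj.astype(np.uint8))

    def adjacency_matrix(self) -> np.ndarray:
        if self.adjacency is not None:
            return self.adjacency
        adj = np.ones((self.N, self.N), dtype=np.uint8)
        np.fill_diagonal(adj, 0)
        return adj

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt


@dataclass
class AgentState:
    """Per-agent dynamical state."""

    V: float
    eps: int
    Tb: float
    Td: float

    @property
    def Ts(self) -> float:
        return self.Tb - self.Td

    def validate(self) -> None:
        if not 0.0 <= self.V <= 1.0:
            raise ValueError("V out of [0, 1]")
        if self.eps not in (0, 1):
            raise ValueError("eps must be 0 or 1")
        if self.Td <= 0 or self.Ts <= 0:
            raise ValueError("need Td > 0 and Ts = Tb - Td > 0")


@dataclass(frozen=True)
class FlashSeries:
    """Flash events (agent id, start, end), ordered by start time."""

    agent_id: np.ndarray
    t_start: np.ndarray
    t_end: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        a = np.asarray(self.agent_id, dtype=np.int64)
        s = np.asarray(self.t_start, dtype=float)
        e = np.asarray(self.t_end, dtype=float)
        if not (a.shape == s.shape == e.shape):
            raise ValueError("mismatched record arrays")
        if np.any(e <= s):
            raise ValueError("flash end must follow its start")
        order = np.argsort(s, kind="stable")
        object.__setattr__(self, "agent_id", a[order])
        object.__setattr__(self, "t_start", s[order])
        object.__setattr__(self, "t_end", e[order])
        for agent in np.unique(a):
            sel = self.agent_id == agent
            if np.any(self.t_start[sel][1:] < self.t_end[sel][:-1]):
                raise ValueError(f"overlapping flashes for agent {agent}")

    def __len__(self) -> int:
        return int(self.agent_id.size)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"agent_id": self.agent_id,
                             "t_start": self.t_start, "t_end": self.t_end})


def _sampling_tables(b: IBIDensity, d: FlashLengthDensity):
    """(times, cdf) tables for inverse-CDF draws inside the kernel."""
    return (b.times, b.cdf_grid(), d.times, d.cdf_grid())


def _check_compatible(b: IBIDensity, d: FlashLengthDensity) -> None:
    if d.t_min >= b.t_max:
        raise ValueError(
            "flash-length floor exceeds the IBI ceiling: Tb > Td is unsatisfiable")


@njit(cache=True)
def _draw(times, cdf, u):
    return np.interp(u, cdf, times)


@njit(cache=True)
def _draw_pair(tb_t, tb_c, td_t, td_c):
    # rejection-sample (Tb, Td) until Tb > Td so Ts = Tb - Td > 0
    for _ in range(_MAX_RESAMPLE_TRIES):
        tb = _draw(tb_t, tb_c, np.random.random())
        td = _draw(td_t, td_c, np.random.random())
        if tb > td:
            return tb, td
    raise ValueError("could not satisfy Tb > Td")


@njit(cache=True)
def _run_kernel(n_steps, dt, beta, adj, V, eps, Tb, Td,
                tb_t, tb_c, td_t, td_c, seed,
                out_agent, out_start, out_end):
    np.random.seed(seed)
    N = V.shape[0]
    # init: all charging, uniform voltage, per-agent (Tb, Td) with Tb > Td
    for i in range(N):
        V[i] = np.random.random()
        eps[i] = 1
        tb, td = _draw_pair(tb_t, tb_c, td_t, td_c)
        Tb[i] = tb
        Td[i] = td
    open_idx = np.full(N, -1, np.int64)
    n_flash = 0
    cap = out_agent.shape[0]
    eps_snap = np.empty(N, np.uint8)
    for k in range(n_steps):
        t = k * dt
        # (1) threshold crossings
        for i in range(N):
            if eps[i] == 1 and V[i] >= 1.0:
                eps[i] = 0
                if n_flash >= cap:
                    raise ValueError("flash buffer overflow")
                out_agent[n_flash] = i
                out_start[n_flash] = t
                out_end[n_flash] = -1.0
                open_idx[i] = n_flash
                n_flash += 1
            elif eps[i] == 0 and V[i] <= 0.0:
                eps[i] = 1
                out_end[open_idx[i]] = t
                open_idx[i] = -1
                tb, td = _draw_pair(tb_t, tb_c, td_t, td_c)
                Tb[i] = tb
                Td[i] = td
        # (2)+(3) synchronous voltage update; eps_i = 0 means flashing now
        for i in range(N):
            eps_snap[i] = eps[i]
        for i in range(N):
            if eps_snap[i] == 1:
                s = 0.0
                for j in range(N):
                    if adj[i, j] == 1 and eps_snap[j] == 0:
                        s += 1.0
                V[i] += dt * (1.0 / (Tb[i] - Td[i]) + (beta / N) * s)
                if V[i] > 1.0:
                    V[i] = 1.0
            else:
                V[i] -= dt / Td[i]
                if V[i] < 0.0:
                    V[i] = 0.0
    return n_flash


def init_swarm(config: SwarmConfig, b: IBIDensity, d: FlashLengthDensity,
               rng: np.random.RandomState | None = None) -> list[AgentState]:
    """Reference initialization: all agents charging, V ~ U[0, 1).

    Mirrors the kernel's internal initialization (same legacy RNG stream
    seeded with ``config.seed``) so the returned states match what
    ``simulate`` starts from; pass ``rng`` to keep consuming the same
    stream in subsequent ``step`` calls.
    """
    _check_compatible(b, d)
    tb_t, tb_c, td_t, td_c = _sampling_tables(b, d)
    if rng is None:
        rng = np.random.RandomState(config.seed)
    agents = []
    for _ in range(config.N):
        v = rng.random_sample()
        for _ in range(_MAX_RESAMPLE_TRIES):
            tb = float(np.interp(rng.random_sample(), tb_c, tb_t))
            td = float(np.interp(rng.random_sample(), td_c, td_t))
            if tb > td:
                break
        else:
            raise ValueError("could not satisfy Tb > Td")
        agents.append(AgentState(V=v, eps=1, Tb=tb, Td=td))
    return agents


def step(agents: list[AgentState], config: SwarmConfig, t: float,
         b: IBIDensity, d: FlashLengthDensity,
         rng: np.random.RandomState) -> tuple[list[AgentState], list[tuple]]:
    """One reference timestep; returns (updated agents, events).

    Events are ("start" | "end", agent index, t).  Agents are updated in
    place; the voltage update reads a synchronous snapshot of eps taken
    after the threshold pass, so agent ordering cannot matter.
    """
    tb_t, tb_c, td_t, td_c = _sampling_tables(b, d)
    adj = config.adjacency_matrix()
    events = []
    for i, a in enumerate(agents):
        if a.eps == 1 and a.V >= 1.0:
            a.eps = 0
            events.append(("start", i, t))
        elif a.eps == 0 and a.V <= 0.0:
            a.eps = 1
            events.append(("end", i, t))
            for _ in range(_MAX_RESAMPLE_TRIES):
                tb = float(np.interp(rng.random_sample(), tb_c, tb_t))
                td = float(np.interp(rng.random_sample(), td_c, td_t))
                if tb > td:
                    break
            else:
                raise ValueError("could not satisfy Tb > Td")
            a.Tb, a.Td = tb, td
    eps_snap = np.array([a.eps for a in agents], dtype=np.uint8)
    flashing = (eps_snap == 0).astype(float)
    for i, a in enumerate(agents):
        if eps_snap[i] == 1:
            pull = (config.beta / config.N) * float(adj[i] @ flashing)
            a.V = min(a.V + config.dt * (1.0 / a.Ts + pull), 1.0)
        else:
            a.V = max(a.V - config.dt / a.Td, 0.0)
    return agents, events


def simulate(config: SwarmConfig, b: IBIDensity,
             d: FlashLengthDensity) -> FlashSeries:
    """Run the swarm for ``config.n_steps`` timesteps of ``config.dt``.

    Returns every completed flash (events still open at the end of the run
    are dropped).  Bit-identical output for identical inputs and seed.
    """
    _check_compatible(b, d)
    tb_t, tb_c, td_t, td_c = _sampling_tables(b, d)
    N = config.N
    # capacity: each flash lasts at least d.t_min plus one charging step,
    # so that bounds the per-agent flash rate even under strong coupling
    cap = int(N * (config.duration / max(d.t_min + config.dt, 2 * config.dt) + 2)) + 16
    out_agent = np.empty(cap, np.int64)
    out_start = np.empty(cap, np.float64)
    out_end = np.empty(cap, np.float64)
    V = np.empty(N, np.float64)
    eps = np.empty(N, np.uint8)
    Tb = np.empty(N, np.float64)
    Td = np.empty(N, np.float64)
    n_flash = _run_kernel(
        config.n_steps, config.dt, config.beta, config.adjacency_matrix(),
        V, eps, Tb, Td, tb_t, tb_c, td_t, td_c, config.seed,
        out_agent, out_start, out_end)
    closed = out_end[:n_flash] > 0
    return FlashSeries(agent_id=out_agent[:n_flash][closed],
                       t_start=out_start[:n_flash][closed],
                       t_end=out_end[:n_flash][closed],
                       duration=config.duration)


def run_replicates(config: SwarmConfig, b: IBIDensity, d: FlashLengthDensity,
                   n_trials: int) -> list[FlashSeries]:
    """Independent trials; trial k reuses the config with seed + k."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return [simulate(replace(config, seed=config.seed + k), b, d)
            for k in range(n_trials)]
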