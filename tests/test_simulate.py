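import numpy as np
import pytest

import fireflysync as ff
from fireflysync.simulate import init_swarm, step


class TestSwarmConfig:
    def test_default_scale_is_thirty_minutes(self):
        cfg = ff.SwarmConfig(N=1, beta=0.0)
        assert cfg.n_steps * cfg.dt == pytest.approx(1800.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            ff.SwarmConfig(N=0, beta=0.0)
        with pytest.raises(ValueError):
            ff.SwarmConfig(N=2, beta=-0.1)
        with pytest.raises(ValueError):
            ff.SwarmConfig(N=2, beta=0.0, adjacency=np.eye(2))  # nonzero diag
        with pytest.raises(ValueError):
            ff.SwarmConfig(N=3, beta=0.0,
                           adjacency=np.triu(np.ones((3, 3)), 1))  # asymmetric

    def test_default_adjacency_all_to_all(self):
        adj = ff.SwarmConfig(N=4, beta=0.0).adjacency_matrix()
        assert adj.sum() == 12 and np.all(np.diag(adj) == 0)


class TestInitSwarm:
    def test_reproducible_and_valid(self, lognormal_density, flash_density):
        cfg = ff.SwarmConfig(N=8, beta=0.0, seed=9)
        a = init_swarm(cfg, lognormal_density, flash_density)
        b = init_swarm(cfg, lognormal_density, flash_density)
        assert [(x.V, x.Tb, x.Td) for x in a] == [(x.V, x.Tb, x.Td) for x in b]
        for agent in a:
            agent.validate()
            assert 0.0 <= agent.V < 1.0
            assert agent.eps == 1
            assert agent.Ts > 0

    def test_unsatisfiable_flash_length_rejected(self, flash_density):
        t = np.arange(0, 0.11, 0.01)
        tiny_b = ff.IBIDensity.from_values(
            t, ((t >= 0.01) & (t <= 0.1)).astype(float), t_min=0.01, t_max=0.1,
            grid_step=0.01)
        cfg = ff.SwarmConfig(N=2, beta=0.0)
        with pytest.raises(ValueError, match="unsatisfiable"):
            init_swarm(cfg, tiny_b, flash_density)


def _delta_density(center, width=0.1, step=0.1, t_max=None, cls=ff.IBIDensity):
    t_max = t_max or center + 5 * width
    t = np.arange(0, t_max + step / 2, step)
    dens = ((t >= center) & (t <= center + width)).astype(float)
    return cls.from_values(t, dens, t_min=center, t_max=center + width,
                           grid_step=step)


class TestStep:
    def test_single_agent_period_is_tb(self):
        # near-delta Tb = 10 s, Td = 1 s: flash starts every ~10 s
        b = _delta_density(10.0)
        d = _delta_density(1.0, cls=ff.FlashLengthDensity)
        cfg = ff.SwarmConfig(N=1, beta=0.0, n_steps=60_000, seed=2)
        fs = ff.simulate(cfg, b, d)
        intervals = np.diff(fs.t_start)
        assert len(intervals) >= 4
        assert np.all(np.abs(intervals - 10.05) < 0.2 + 2 * cfg.dt)

    def test_charging_gain_includes_neighbor_pull(self, lognormal_density,
                                                  flash_density):
        cfg = ff.SwarmConfig(N=2, beta=0.5, dt=0.009)
        agents = [ff.AgentState(V=0.5, eps=1, Tb=20.0, Td=1.0),
                  ff.AgentState(V=0.5, eps=0, Tb=20.0, Td=1.0)]
        rng = np.random.RandomState(0)
        step(agents, cfg, 0.0, lognormal_density, flash_density, rng)
        # dV = dt * (1/Ts + beta/N) with one flashing neighbor
        assert agents[0].V == pytest.approx(
            0.5 + 0.009 * (1.0 / 19.0 + 0.25), abs=1e-12)

    def test_flashing_agent_ignores_neighbors(self, lognormal_density,
                                              flash_density):
        cfg = ff.SwarmConfig(N=2, beta=5.0, dt=0.009)
        agents = [ff.AgentState(V=0.5, eps=0, Tb=20.0, Td=1.0),
                  ff.AgentState(V=0.5, eps=0, Tb=20.0, Td=1.0)]
        rng = np.random.RandomState(0)
        step(agents, cfg, 0.0, lognormal_density, flash_density, rng)
        assert agents[0].V == pytest.approx(0.5 - 0.009 / 1.0, abs=1e-12)

    def test_voltage_stays_bounded(self, lognormal_density, flash_density):
        cfg = ff.SwarmConfig(N=4, beta=2.0, seed=5)
        rng = np.random.RandomState(cfg.seed)
        agents = init_swarm(cfg, lognormal_density, flash_density, rng=rng)
        for k in range(3000):
            agents, _ = step(agents, cfg, k * cfg.dt, lognormal_density,
                             flash_density, rng)
            assert all(0.0 <= a.V <= 1.0 for a in agents)


class TestSimulate:
    def test_bit_identical_given_seed(self, lognormal_density, flash_density):
        cfg = ff.SwarmConfig(N=10, beta=0.3, n_steps=30_000, seed=21)
        a = ff.simulate(cfg, lognormal_density, flash_density)
        b = ff.simulate(cfg, lognormal_density, flash_density)
        assert np.array_equal(a.t_start, b.t_start)
        assert np.array_equal(a.t_end, b.t_end)
        assert np.array_equal(a.agent_id, b.agent_id)

    def test_kernel_agrees_with_reference_step(self, lognormal_density,
                                               flash_density):
        """The compiled engine and the plain-Python step produce the same
        flash sequence when fed the same RNG stream."""
        cfg = ff.SwarmConfig(N=3, beta=0.5, n_steps=20_000, seed=17)
        fs = ff.simulate(cfg, lognormal_density, flash_density)
        rng = np.random.RandomState(cfg.seed)
        agents = init_swarm(cfg, lognormal_density, flash_density, rng=rng)
        starts = []
        for k in range(cfg.n_steps):
            agents, events = step(agents, cfg, k * cfg.dt, lognormal_density,
                                  flash_density, rng)
            starts += [(i, t) for kind, i, t in events if kind == "start"]
        kernel = sorted(zip(fs.agent_id.tolist(), fs.t_start.tolist()),
                        key=lambda x: (x[1], x[0]))
        reference = sorted(starts, key=lambda x: (x[1], x[0]))
        assert kernel == reference[:len(kernel)]

    def test_uncoupled_agents_are_independent(self, lognormal_density,
                                              flash_density):
        cfg = ff.SwarmConfig(N=2, beta=0.0, n_steps=400_000, seed=8)
        fs = ff.simulate(cfg, lognormal_density, flash_density)
        # windowed flash counts of the two agents should be uncorrelated
        edges = np.arange(0.0, cfg.duration + 30.0, 30.0)
        c0 = np.histogram(fs.t_start[fs.agent_id == 0], bins=edges)[0]
        c1 = np.histogram(fs.t_start[fs.agent_id == 1], bins=edges)[0]
        r = np.corrcoef(c0, c1)[0, 1]
        assert abs(r) < 0.15

    def test_flash_records_are_well_formed(self, lognormal_density,
                                           flash_density):
        cfg = ff.SwarmConfig(N=5, beta=0.2, n_steps=100_000, seed=31)
        fs = ff.simulate(cfg, lognormal_density, flash_density)
        assert np.all(fs.t_end > fs.t_start)
        assert np.all(np.diff(fs.t_start) >= 0)
        for agent in range(5):
            sel = fs.agent_id == agent
            assert np.all(fs.t_start[sel][1:] >= fs.t_end[sel][:-1])


class TestRunReplicates:
    def test_trials_differ_and_accumulate(self, lognormal_density,
                                          flash_density):
        cfg = ff.SwarmConfig(N=5, beta=0.0, n_steps=50_000, seed=40)
        trials = ff.run_replicates(cfg, lognormal_density, flash_density, 3)
        assert len(trials) == 3
        assert not np.array_equal(trials[0].t_start, trials[1].t_start)
        counts = [len(t) for t in trials]
        assert all(c > 0 for c in counts)

    def test_trial_seeds_are_offsets(self, lognormal_density, flash_density):
        cfg = ff.SwarmConfig(N=3, beta=0.0, n_steps=30_000, seed=50)
        trials = ff.run_replicates(cfg, lognormal_density, flash_density, 2)
        cfg1 = ff.SwarmConfig(N=3, beta=0.0, n_steps=30_000, seed=51)
        direct = ff.simulate(cfg1, lognormal_density, flash_density)
        assert np.array_equal(trials[1].t_start, direct.t_start)
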