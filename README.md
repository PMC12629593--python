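# fireflysync

Emergent collective periodicity from intrinsically aperiodic flashers.

An isolated *Photinus carolinus* firefly emits flash bursts at essentially
random times: the interburst interval (IBI) varies from a few seconds to
tens of minutes. A swarm of them nevertheless flashes with a well-defined
collective period of roughly a dozen seconds. `fireflysync` implements the
extreme-value mechanism behind that paradox, for researchers in collective
animal behavior and coupled-oscillator dynamics:

* **Analytic theory.** If each of `N` fireflies waits a time drawn from a
  density `b(t)` and any flash instantly triggers the rest, the collective
  interburst interval is the *minimum* of `N` waiting times. With the
  survival function `γ(t) = ∫_t^∞ b(t') dt'`, the group density is

  ```
  P_N(T_b) = N γ(T_b)^(N−1) b(T_b),      ⟨T_N^m⟩ = m ∫ γ^N(t) t^(m−1) dt.
  ```

  All moments and the variance strictly decrease with `N`, the left-most
  mode drifts down to the refractory floor `T_0` (the minimum possible
  IBI), and `P_N → δ(T_b − T_0)` as `N → ∞`: periodicity emerges at the
  fastest interval any individual can produce, with no fitting parameter.

* **Stochastic pulse-coupled swarm simulator.** An integrate-and-fire agent
  model where each agent's voltage obeys

  ```
  dV_i/dt = ε_i/T_s,i − (1 − ε_i)/T_d,i + ε_i Σ_j (β/N) δ_ij (1 − ε_j),
  ```

  with `ε_i = 1` while charging and `0` while flashing, start-to-start
  interval `T_b` and flash length `T_d` resampled from their input
  densities at every state switch, and a tunable coupling `β` that pulls
  charging agents toward threshold while neighbors flash.

* **Burst analysis and β fitting.** Flash series → collective bursts
  (connected components of flashes < 2 s apart) → interburst intervals,
  and a two-sample Kolmogorov–Smirnov sweep over `(β, N)` that selects the
  best-fitting coupling per swarm size.

Everything is buildable and testable from the package's own synthetic
generators (shifted-exponential / shifted-lognormal IBI models and a
histogram-spline "envelope" protocol); no field data are required.

## Worked example

The full pipeline from synthetic data, via the command-line interface:

```bash
fireflysync synth --family shifted_lognormal --t0 5.672 --median 30 \
    --sigma 1.0 --n 5000 --seed 1 --out samples.csv
fireflysync envelope samples.csv --out density.csv
fireflysync theory density.csv --n 20 --outdir theory_out
fireflysync simulate density.csv --n 20 --beta 0.3 --steps 200000 \
    --seed 1 --outdir sim_out
fireflysync analyze sim_out/flashes_trial0.csv --outdir analysis
```

The `theory` step prints

```
N=20 mean=8.217s std=1.923s mode=6.3s
```

the idealized (instant-triggering) prediction: twenty fireflies whose
individual IBIs spread over minutes (`std_vs_N.csv` starts at
`N=1, std=51.4 s, mean=45.2 s`) should produce collective bursts every
~8.2 s with only ~1.9 s of spread — the emergent period. The `analyze`
step prints the simulated swarm's measured intervals at moderate coupling
`β = 0.3`:

```
311 intervals  mode=3.25s mean=5.77s std=2.99s
```

shorter and noisier than the ideal limit because at this coupling a flash
recruits only part of the swarm — the transition toward full entrainment
is exactly what the β sweep (`fireflysync sweep`) quantifies.

The same operations are available as a library
(`fireflysync.group_density`, `fireflysync.simulate`,
`fireflysync.beta_sweep`, ...); see `docs/methods.md` for the model
details, numerical choices and known limitations.

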