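# Methods

## Model and assumptions

The package studies how a collective flashing period emerges in groups of
individuals that are aperiodic in isolation. Two linked descriptions are
implemented.

**Extreme-value (first-to-flash) theory.** Each individual, after a
collective burst, waits a time drawn independently from a density `b(t)`
with a hard minimum `t_min` (the refractory floor) before flashing; a flash
instantly triggers every other individual, which then resets. The
collective interburst interval is therefore the minimum of `N` draws,

```
P_N(t) = N γ(t)^(N−1) b(t),        γ(t) = ∫_t^∞ b(t') dt',
```

and in the heterogeneous case `P_N(t) = Σ_i b_i(t) Π_{j≠i} γ_j(t)`.
Raw moments are computed as `⟨T_N^m⟩ = m ∫ γ^N(t) t^(m−1) dt`, which
assumes `b` has bounded support (true of every gridded density here).
Consequences verified by the test suite: all moments strictly decrease in
`N`, the variance is monotone non-increasing, the left-most mode moves
left until it reaches `t_min`, and the distribution concentrates at
`t_min` as `N → ∞`.

**Stochastic pulse-coupled integrate-and-fire swarm.** Agent `i` carries a
voltage `V_i ∈ [0, 1]` and a binary state `ε_i` (1 charging, 0 flashing):

```
dV_i/dt = ε_i/T_s,i − (1 − ε_i)/T_d,i + ε_i Σ_j (β/N) δ_ij (1 − ε_j)
```

`T_b` (start-to-start interval) and `T_d` (flash length) are resampled
from their densities at every switch back to charging, with `T_s = T_b −
T_d` enforced positive by rejection. `δ` is a binary, symmetric,
zero-diagonal adjacency (all-to-all by default); the pair coupling is
`β/N` regardless of adjacency. `β = 0` gives independent renewal
flashers; increasing `β` lets flashes recruit neighbors and entrains the
swarm.

## Parameters

| parameter | default | meaning |
|---|---|---|
| cleaning cutoff | 2.0 s | intervals below this are within-burst gaps, not IBIs |
| histogram bins | 50 | envelope protocol bin count |
| grid step | 0.1 s | density grid resolution |
| burst gap | 2.0 s | start-to-start threshold joining flashes into bursts |
| `dt` | 0.009 s | timestep; 200 000 steps span 30 min |
| `n_steps` | 200 000 | steps per simulation trial |
| burn-in | 5 bursts | discarded per trial before pooling intervals |
| β grid | 0–1, step 0.02 | coupling sweep range |
| trials per sweep cell | 10 | replicates pooled before the KS test |
| summary bin width | 0.5 s | histogram resolution for interval modes |

## Synthetic data

The generators emulate the statistical shape of isolated-firefly data
without bundling any measurements:

* canonical IBI model (`default_ibi_model`): shifted lognormal, floor
  5.672 s, median 30 s, log-σ 1.0, truncated at 1400 s — heavy right tail
  spanning seconds to tens of minutes, matching the observed range of
  isolated-individual intervals;
* flash-length stand-in (`default_flash_length_density`): shifted
  lognormal, floor 0.2 s, median 1.0 s, log-σ 0.3, capped at 3 s. This is
  a synthetic placeholder for the published flash-length measurements,
  which are not redistributed here.

What the generators do *not* emulate: multi-flash trains within a burst
(each simulated burst is a single discharge), temperature dependence,
inter-individual heterogeneity of `b`, spatial structure and occlusion,
and perception delays. Tests passing on these inputs therefore validate
the algorithms and the theory–simulation relationship, not field-data
fidelity.

## The envelope protocol

Raw interval lists are cleaned (drop values below 2.0 s), histogrammed
into 50 uniform density bins on `[min, max]`, interpolated by a natural
cubic spline through the bin centers, evaluated on the 0.1 s grid,
zero-padded on `[0, min)`, clipped at zero where the spline undershoots,
and renormalized to unit trapezoid area. Natural boundary conditions and
zero-clipping are this package's choices where the protocol is silent;
the last histogram bin is right-closed so the maximum sample is counted.

## Numerical choices

* **Grid semantics.** Densities are piecewise linear between grid points;
  `integral()` and normalization use the trapezoid rule on the full grid.
* **Support-jump CDF.** A density with a refractory floor is *discontinuous*
  at `t_min`; the trapezoid rule would smear mass `≈ ½·Δt·b(t_min)` into
  the cell just below it. Raised to the power `N`, that error dominates
  group statistics (a 33 % variance error at `N = 50` on the default
  grid). `cdf_grid()` therefore assigns zero mass to cells below `t_min`
  and only the `[t_min, edge]` share to the straddling cell; sampling,
  survival curves and moments inherit the correction.
* **Resolution.** The group distribution's width shrinks like `1/N`
  (width `1/(Nλ)` for a shifted exponential), so closed-form comparisons
  at `N = 50` use a 0.01 s grid; the 0.1 s default cannot resolve a
  0.1 s-wide distribution.
* **Sampling** is inverse-CDF on the piecewise-linear CDF — the
  continuous analogue of resampling the fine-grained envelope, avoiding
  grid-cell artifacts — with draws clipped to `[t_min, t_max]`.
* **Simulator integration** is forward Euler with voltages clamped to
  `[0, 1]` and threshold crossings handled at step granularity. Per step:
  (1) threshold crossings flip `ε` (and flash ends trigger resampling);
  (2) agents with `ε = 0` are flashing; (3) voltages update from a
  synchronous snapshot of `ε`, so agent ordering cannot matter. The
  coupling term is a rate (per second) integrated with the same Euler
  step. The hot loop is a numba kernel; a plain-Python `step` implements
  the identical update and the test suite checks the two produce the same
  flash sequence from the same RNG stream.
* **Initialization** draws `V ~ U[0, 1)` with all agents charging
  (the model itself does not prescribe a start state), and analyses
  discard the first 5 collective bursts to shed the transient.
* **Mode detection** uses the raw grid (first positive grid point
  exceeding its left neighbor and not below its right one; ties resolve
  to smaller times). Strict monotonicity assertions use a `1e-9`
  tolerance for floating-point noise.
* **KS fitting** pools replicate trials into one sample before the
  two-sided two-sample test (asymptotic p-values); the best `β` per `N`
  is the argmin of `D`, ties toward smaller `β`.

## Problem sizes used by the test suite

Closed-form and oracle checks use `10^5`–`10^6` Monte-Carlo draws. The
renewal-limit check runs a single uncoupled agent for `10^7` steps
(≈ 25 h of simulated time, ≈ 2000 bursts), enough that the finite-sample
KS fluctuation (≈ 0.02) sits well below the 0.05 acceptance bound — at
the 150-burst minimum the expected KS distance of a *correct*
implementation (≈ 0.07) would already exceed that bound. Coupling-strength
recovery runs the full β grid (0–1, step 0.02) with 10 pooled trials of
200 000 steps per cell, recovering generating values 0.2 and 0.3 within
one grid step; the faster unit test uses a 0.04 grid with 8 trials.

## Known limitations

* **The strong-coupling limit is singular.** Conceptually, `β → ∞`
  reproduces the first-to-flash theory (one flash instantly triggers the
  whole swarm). In the discretized dynamics it does not: the coupling
  strong enough to recruit low-voltage agents within one flash length is
  also strong enough to re-trigger agents the moment they finish
  discharging, because staggered flash ends always leave some neighbor
  flashing. Beyond `β ≈ 2` (study conditions, `N = 20`) the swarm enters
  a self-sustaining "chatter" state with no quiet gaps and hence no
  detectable bursts; below it, burst participation is partial and the
  best simulated-vs-analytic KS distance is ≈ 0.3. The corresponding
  acceptance test documents this gap and fails by design rather than
  asserting a weakened bound. Physiologically the gap reflects a missing
  refractory mechanism: a real firefly cannot be induced to restart a
  burst immediately after finishing one.
* Group-interval definitions (burst-based vs flash-to-flash) coincide
  only in well-synchronized regimes; both are exposed and tagged.
* The asymptotic KS p-value is inaccurate for very small samples; `D`
  itself is always exact.
* Heterogeneous-group support bounds are asymptotic statements; tests
  check the limiting support only, not a convergence rate.
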