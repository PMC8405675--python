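# Methods

## Model and assumptions

The body is two well-mixed thermal compartments. Skin relaxes linearly toward
both air and core; the core exchanges heat with the skin, loses heat to the
air through breathing (coefficient `k4 · V_O2`, assumed much smaller than the
other rates), and is actively regulated by the saturating feedback
`f_S(T_C) = p u e^{−v u²}`, `u = T_C_set − T_C`. The five structural
requirements on any admissible feedback are: smoothness; zero at the set
point; heating below / cooling above the set point; decay to (approximately)
zero outside an effective support `[θ1, θ2]`; and a single maximum below and
a single minimum above the set point. The Gaussian-kernel form satisfies all
five and is additionally odd about the set point, but no symmetry is assumed
anywhere: `CustomSaturation` accepts any value/derivative pair meeting the
five requirements, with the area then computed by quadrature instead of the
closed form `p/v`.

There is no humidity, radiation, clothing, sweating, or noise term, and no
delay; the model's point is the *qualitative* mechanism — finite regulatory
reach produces a second stable state and hysteresis — not heat-balance
realism.

## Parameters

| name | meaning | unit | default |
|---|---|---|---|
| k1 | skin–air exchange rate | 1/min | 0.2 |
| k2 | core→skin influence on skin | 1/min | 0.2 |
| k3 | skin→core exchange rate | 1/min | 0.2 |
| k4 | breathing loss per litre O2 | 1/l | 0.06 |
| V_O2 | oxygen uptake | l/min | 0.3 |
| T_A | ambient air temperature | K | 300 |
| p | feedback peak scale | 1/min | 2 |
| v | reciprocal variability | 1/K² | 0.5 |
| T_C_set | core set point | K | 310.15 |

These are the reference values shipped as the `table2_table3_defaults`
preset. The unit of `k4` alone is taken as stated (1/l); only the product
`k4·V_O2` (1/min) enters the dynamics, which is also why the dimensionless
reduction `τ = k1 t`, `a = k2/k1`, `b = k3/k1`, `c = p/k1`, `d = k4 V_O2/k1`
cannot recover `k4` and `V_O2` individually.

## Numerical choices

**Equilibria.** The branch relation `T_A(T_C*) = T_C* − C f_S(T_C*)` is
explicit, so equilibrium finding is global bracketing on a 0.01 K grid over
`T_C_set ± max(25 K, |T_A − T_C_set| + 10 K)` followed by bisection to
1e−10 K — complete by construction, with no continuation machinery. A point
counts as an equilibrium when the vector-field residual is below 1e−9 K/min.

**Folds.** Since `C · (k1 k3/(k1+k2) + k4 V_O2) = 1` identically, the
stability-condition equality coincides with `dT_A/dT_C* = 0`: folds are the
stationary points of the explicit branch map. `f_S'` is even in `u` with
extrema exactly at `u = 0` and `u² = 3/(2v)`, so the up-to-two roots per side
are bisected on analytically bracketed monotone segments (tolerance
1e−10 K). If the peak slope `2p e^{−3/2}` does not exceed the threshold, the
model is mono-stable for every ambient temperature and the fold set is empty.
This sweep-in-`T_C*` strategy deliberately replaces generic continuation
software: for this model it is exact and simpler.

**Labels.** Unstable fixed points are saddles (the only unstable type the
planar model admits). "Homeostatic" is made quantitative as: stable and at
least as close (in core temperature) to the set point as to ambient
temperature; ties resolve to homeostatic. This is a package convention — only
"close to" is inherent in the model. A parameter point sitting exactly on a
fold (two equilibria) classifies into the adjacent bi-stable area 3.

**Verge tables.** Reported verges are rounded to the 0.5 K grid the reference
tables use; the raw high-precision values are kept alongside (`*_raw`
columns). Recomputed verges can differ from the printed estimates by up to
~0.5 K (the tables were produced by numerical continuation at an unstated
resolution), so comparisons use a ±0.75 K tolerance.

**Integration.** `solve_ivp` (LSODA by default) at rtol 1e−8 / atol 1e−10,
with an optional run-to-convergence event stopping when `max|rhs| <
1e−9 K/min`; non-convergence within the horizon is flagged, not raised.

**Hysteresis.** "Slowly varying ambient temperature" is made precise as a
quasi-static protocol: relax to residual < 1e−8 K/min, step `T_A` by 0.1 K
(default), repeat. A jump is a change of converged core temperature exceeding
1 K between consecutive steps — far above solver noise, well below the ≥ 2 K
branch separation at the folds. Jump temperatures therefore overshoot the
verge by at most one step and converge to it as the step shrinks. A
continuous-ramp mode (`ramp_continuous`, rate in K/min) exists for realism
studies; its jumps lag the fold slightly because relaxation takes finite
time.

**Separatrix and basins.** The saddle's stable manifold is traced by
integrating the time-reversed field from `saddle ± ε v_stable` (ε = 1e−6 K)
until leaving the phase window (set point ± 30 K by default), at tight
tolerance (rtol 1e−10). Basin maps integrate each grid point to convergence
and label it by the nearest stable equilibrium; both operations require the
bi-stable area 3 and raise otherwise.

## What a green test establishes — and what it does not

There is no synthetic-data generator: the model itself is the stated world,
and all inputs are the printed reference parameters. Green tests establish
that the implementation reproduces the model's internal mathematics (fold
locations, table values, hysteresis structure, basin geometry) at the stated
tolerances. They establish nothing about real human thermophysiology: the
exchange rates are illustrative, not estimated from data, and the model omits
every transport mechanism beyond the three linear couplings and the single
feedback term.

## Known limitations

- Only fold bifurcations are detected; no Hopf or codimension-2 analysis
  (the model exhibits none at physiological parameters).
- The labeling convention can in principle mislabel a stable equilibrium
  when ambient temperature is very near the set point, where "near set
  point" and "near ambient" coincide; there the distinction is physically
  moot.
- `region_map` border curves are exact only when the scanned axis is `T_A`
  (the explicit fold method applies); otherwise they are grid-edge midpoints
  at the map's resolution.
- The quasi-static ramp reports the first jump only; ramps crossing both
  bands should be run piecewise.
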