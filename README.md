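# thermoreg

A small, well-tested Python library for a **bi-stable two-compartment model of
human thermoregulation**. It is aimed at physiologists and modellers who want
to reason quantitatively about *when homeostasis fails*: for which ambient
temperatures a second, non-homeostatic stable state (core temperature pinned
near air temperature — the "failure" state) coexists with the homeostatic one,
where the fold bifurcations bounding that bi-stable band lie, and how
hysteresis decides which state the body occupies.

## The model

Two state variables, skin temperature `T_S` and core temperature `T_C`
(Kelvin), exchange heat with each other and with ambient air at `T_A`:

```
dT_S/dt = k1 (T_A − T_S) + k2 (T_C − T_S)
dT_C/dt = k3 (T_S − T_C) + f_S(T_C) + k4 V_O2 (T_A − T_C)
```

`k1..k3` are exchange rates (1/min), `k4 V_O2` the breathing heat loss
(breathing coefficient × oxygen uptake). Internal thermoregulation is the
saturating feedback

```
f_S(T_C) = p (T_C_set − T_C) exp(−v (T_C_set − T_C)²),
```

which pulls the core toward the set point `T_C_set = 310.15 K` but has finite
reach — its total capacity is the area `E_S = ∫|f_S| dT_C = p/v`. Because the
feedback vanishes far from the set point, equilibria solve the explicit branch
relation

```
T_A = T_C* − C f_S(T_C*),     C = (k1+k2)/(k1 k3 + k4 V_O2 (k1+k2)),
```

and a fixed point is stable iff `f_S'(T_C*) < k1 k3/(k1+k2) + k4 V_O2`. The
equality case marks the **fold (saddle-node) points**; mapped through the
branch relation they give the **allostatic verges** — the ambient temperatures
where the bi-stable band begins and ends, and where the quasi-static
hysteresis loop jumps.

The package provides:

- `model` — the vector field, the saturating function (value, derivative,
  area), and the nine-to-seven dimensionless parameter reduction `τ = k1 t`;
- `equilibria` — all fixed points at a given `T_A`, Jacobians, the scalar
  stability condition, homeostatic/saddle/non-homeostatic labels, and the
  sensitivity `dT_C*/dT_A`;
- `bifurcation` — fold points and verges, stability-area classification
  (area 1 = homeostatic only, 2 = failure only, 3 = bi-stable), verge tables
  over `V_O2` and over equal-area saturation shapes, two-parameter region
  maps;
- `dynamics` — adaptive integration, quasi-static and continuous hysteresis
  ramps, the saddle separatrix, and basin-of-attraction maps;
- `config` — JSON run configs, the packaged `table2_table3_defaults`
  parameter preset, and CSV/JSON artifact writers.

## Worked example

```python
from thermoreg import ThermoParams, SaturationShape, find_equilibria, \
    fold_points, ramp_protocol

params, shape = ThermoParams(), SaturationShape()

for eq in find_equilibria(params.with_(T_A=303.0), shape):
    print(f"{eq.T_C_star:8.4f} K  {'stable' if eq.stable else 'saddle'}  {eq.label}")

for pt in sorted(fold_points(params, shape).points, key=lambda p: p.T_A):
    print(f"border {pt.border}: verge T_A = {pt.T_A:.4f} K")

up = ramp_protocol(295.0, 310.0, params, shape, step=0.1)
print(f"warming jump at {up.jump_T_A:.1f} K")
```

prints

```
303.0000 K  stable  non_homeostatic
308.2426 K  saddle  saddle
309.7144 K  stable  homeostatic
border 2-3: verge T_A = 298.8451 K
border 3-1: verge T_A = 306.6267 K
border 1-3: verge T_A = 313.6733 K
border 3-2: verge T_A = 321.4549 K
warming jump at 306.7 K
```

At 303 K air three equilibria coexist: the body can settle warm (core
309.71 K, homeostatic) or cold (core ≈ air, the failure state), separated by a
saddle. The bi-stable band is bounded by the four verges; a slow warming ramp
started on the cold branch jumps to the homeostatic branch at the 306.6 K
fold, while a slow cooling ramp holds out down to 298.8 K — an ~8 K
hysteresis loop. The `examples/` directory holds one short narrative script
per capability (equilibria, verge tables, hysteresis, basins/separatrix,
parameter reduction).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged reference parameters alone, the three fold
verges of the bi-stable band (borders 3–1, 3–2 and 2–3, on the 0.5 K
reporting grid) and the area below the saturation curve for the wide
reference shape (closed form cross-checked by quadrature), and writes them as
JSON.
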