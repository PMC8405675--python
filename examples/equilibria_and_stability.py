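"""Find and classify all equilibria at one ambient temperature.

At 303 K air (inside the cold bi-stable band) the model has three fixed
points: a stable non-homeostatic one with the core near air temperature, a
saddle, and a stable homeostatic one with the core near the 310.15 K set
point. The sensitivity dT_C*/dT_A says how much the homeostatic core drifts
per Kelvin of ambient change — small means good regulation.
"""

from thermoreg import ThermoParams, SaturationShape, find_equilibria, homeostatic_sensitivity

params = ThermoParams(T_A=303.0)
shape = SaturationShape()

print(f"Equilibria at T_A = {params.T_A} K:")
for eq in find_equilibria(params, shape):
    eig = ", ".join(f"{e.real:+.4f}" for e in eq.eigenvalues)
    print(
        f"  T_C* = {eq.T_C_star:8.4f} K   T_S* = {eq.T_S_star:8.4f} K   "
        f"eigenvalues ({eig}) 1/min   {'stable  ' if eq.stable else 'unstable'} "
        f"{eq.label}"
    )

home = [e for e in find_equilibria(params, shape) if e.label == "homeostatic"][0]
s = homeostatic_sensitivity(home, params, shape)
print(f"\nHomeostatic sensitivity dT_C*/dT_A = {s:.4f} (dimensionless)")
print("-> the core moves only ~%.1f mK per K of ambient change." % (1000 * s))
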