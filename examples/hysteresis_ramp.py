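"""Quasi-static hysteresis: warming and cooling jump at different verges.

Warming the air slowly from 295 K, the body tracks the non-homeostatic
(failure) branch until that branch is annihilated at a fold near 306.6 K
and the state jumps up to the homeostatic branch. Cooling back from 305 K,
the homeostatic branch survives down to ~298.8 K before the downward jump.
The two jump temperatures differ: the loop encloses the bi-stable band.
"""

from thermoreg import ThermoParams, SaturationShape, ramp_protocol

params = ThermoParams()
shape = SaturationShape()

up = ramp_protocol(295.0, 310.0, params, shape, step=0.1)
print(
    f"warming ramp 295 -> 310 K: jump at T_A = {up.jump_T_A:.1f} K "
    f"({up.branch_before} -> {up.branch_after})"
)

down = ramp_protocol(305.0, 295.0, params, shape, step=0.1)
print(
    f"cooling ramp 305 -> 295 K: jump at T_A = {down.jump_T_A:.1f} K "
    f"({down.branch_before} -> {down.branch_after})"
)

print(
    f"hysteresis band width: {up.jump_T_A - down.jump_T_A:.1f} K "
    "(history decides which state the body occupies inside it)"
)
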