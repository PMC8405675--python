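"""Locate the allostatic verges and regenerate the verge tables.

The four fold (saddle-node) points bound the bi-stable band in ambient
temperature: sweeping T_A upward the stability areas run
2 (failure only) -> 3 (both) -> 1 (homeostatic only) -> 3 -> 2.
The two scans show how the verges move with oxygen consumption and with
the shape of the saturating function at fixed regulatory area E_S = 4.
"""

from thermoreg import ThermoParams, SaturationShape, fold_points, scan_vo2, scan_shape

params = ThermoParams()
shape = SaturationShape()

print("Fold points at the reference parameters:")
for pt in sorted(fold_points(params, shape).points, key=lambda p: p.T_A):
    print(
        f"  border {pt.border}:  fold core T_C = {pt.T_C:8.4f} K -> "
        f"verge T_A = {pt.T_A:8.4f} K   ({pt.role})"
    )

print("\nVerges vs oxygen consumption (rounded to 0.5 K):")
cols = ["V_O2", "area_2_3", "area_3_1", "area_1_3", "area_3_2"]
print(scan_vo2(params, shape, [0.1, 0.4, 0.7])[cols].to_string(index=False))

print("\nVerges vs saturation shape at fixed area E_S = 4 K^2/min (p = 4v):")
cols = ["v", "p", "area_2_3", "area_3_1", "area_1_3", "area_3_2"]
print(scan_shape(params, 4.0, [0.1, 0.5, 1.0])[cols].to_string(index=False))
print("-> taller, narrower regulation (larger v) widens the bi-stable band.")
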