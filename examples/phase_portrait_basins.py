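"""Separatrix and basins of attraction inside the bi-stable band.

At 303 K air two attractors coexist. The saddle's stable manifold (the
separatrix) divides the (T_S, T_C) phase plane into the basin of the
homeostatic equilibrium (above) and of the non-homeostatic one (below):
the same ambient conditions can end alive-warm or fatally cold depending
only on the starting temperatures.
"""

import numpy as np

from thermoreg import ThermoParams, SaturationShape, basin_map, separatrix

params = ThermoParams(T_A=303.0)
shape = SaturationShape()

sep = separatrix(params, shape).separatrix
print(f"separatrix polyline: {len(sep)} points, "
      f"T_C from {sep[:,1].min():.2f} to {sep[:,1].max():.2f} K")

part = basin_map(params, shape, T_S_range=(298.0, 316.0),
                 T_C_range=(298.0, 316.0), n=9)
frac = np.mean(part.labels == "homeostatic")
print(f"basin map 9x9 over [298,316]^2 K: "
      f"{frac:.0%} of cells drain to the homeostatic equilibrium")
print("rows = core temperature (cold to warm), H = homeostatic basin:")
for j in range(len(part.T_C_values) - 1, -1, -1):
    row = "".join("H" if lbl == "homeostatic" else "." for lbl in part.labels[j])
    print(f"  T_C={part.T_C_values[j]:6.1f}  {row}")
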