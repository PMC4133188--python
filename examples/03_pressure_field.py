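"""Pressure build-up around the needle tip during a constant-rate injection.

Solves the spherically symmetric poro-elastic pressure equation for a
representative subcutis (k = 1e-10 m², K = 1e5 Pa, φ0 = 0.01) at 100 µL/s
and reports how far the over-pressure reaches.
"""

import numpy as np

from penpress import RadialGrid, TissueParams, depot_radius, solve_pressure
from penpress.device_model import FluidProps
from penpress.units import ATM, MBAR, MM, UL_PER_S

params = TissueParams(k=1e-10, K=1e5, phi0=0.01)
grid = RadialGrid(r_inner=0.1 * MM, r_outer=50 * MM, n_cells=200)
sol = solve_pressure(params, 100 * UL_PER_S, FluidProps(), grid,
                     t_eval=np.linspace(0, 2, 41))

tip = (sol.p_tip[-1] - ATM) / MBAR
r10 = depot_radius(sol, fraction=0.1) / MM
res = sol.diagnostics["mass_balance_residual"]

print(f"needle-tip over-pressure after 2 s: {tip:.0f} mbar")
print(f"over-pressure falls to 10% of the tip value at r = {r10:.1f} mm")
print(f"mass-balance residual: {res:.2e} of the injected volume")
# The over-pressure is localized within a few mm of the tip: the injected
# fluid inflates the local pore space and bleeds away radially by Darcy flow.
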