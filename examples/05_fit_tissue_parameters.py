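"""Estimating tissue permeability and bulk modulus from one injection.

The device-derived needle-outlet pressure is matched by the poro-elastic
model's tip pressure, driven by the measured flow rate; least squares over
(log k, log K) recovers the tissue parameters.
"""

import numpy as np

from penpress import fit_tissue_params, tissue_pressure_series
from penpress.device_model import DeviceGeometry, FluidProps, calibrate_spring
from penpress.synthetic import default_spring_family, simulate_injection
from penpress.tissue_pde import TissueParams
from penpress.units import UL

geom, fluid = DeviceGeometry(), FluidProps()
spring = default_spring_family(geom, fluid)(np.random.default_rng(0), 240 * UL)
truth = TissueParams(k=5e-11, K=1e5)

air_a = simulate_injection(spring, "air", geom, fluid, dose=240 * UL, jitter_sd=0, seed=1)
air_b = simulate_injection(spring, "air", geom, fluid, dose=240 * UL, jitter_sd=0, seed=5)
tissue = simulate_injection(spring, truth, geom, fluid, dose=240 * UL, jitter_sd=0, seed=2)

cal = calibrate_spring([air_a.flow, air_b.flow], geom, fluid)
series = tissue_pressure_series(cal, tissue.flow, geom, fluid)
result = fit_tissue_params(series, tissue.flow, geom, fluid)

print(f"true      k = {truth.k:.3g} m²,  K = {truth.K:.3g} Pa")
print(f"recovered k = {result.k_hat:.3g} m²,  K = {result.K_hat:.3g} Pa "
      f"({len(result.trace)} model evaluations, converged={result.converged})")
print(f"relative errors: k {100 * (result.k_hat / truth.k - 1):+.1f}%, "
      f"K {100 * (result.K_hat / truth.K - 1):+.1f}%")
# k sets how easily the fluid percolates away (higher k, lower pressure);
# K sets how much pressure a given pore-space dilation costs.
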