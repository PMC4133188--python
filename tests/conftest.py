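import numpy as np
import pytest
from hypothesis import settings

from penpress.device_model import DeviceGeometry, FluidProps, calibrate_spring
from penpress.synthetic import default_spring_family, simulate_injection
from penpress.tissue_pde import TissueParams
from penpress.units import UL

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geom():
    return DeviceGeometry()


@pytest.fixture(scope="session")
def fluid():
    return FluidProps()


@pytest.fixture(scope="session")
def spring(geom, fluid):
    """One representative pen spring (decelerating air flow ~150 → ~80 µL/s)."""
    rng = np.random.default_rng(0)
    return default_spring_family(geom, fluid)(rng, 240 * UL)


@pytest.fixture(scope="session")
def air_pair(spring, geom, fluid):
    """Two jitter-free air reference injections from the same pen."""
    kw = dict(geom=geom, fluid=fluid, dose=240 * UL, jitter_sd=0.0)
    return (
        simulate_injection(spring, "air", seed=1, **kw),
        simulate_injection(spring, "air", seed=5, **kw),
    )


@pytest.fixture(scope="session")
def tissue_truth():
    return TissueParams(k=5e-11, K=1e5)


@pytest.fixture(scope="session")
def tissue_injection(spring, geom, fluid, tissue_truth):
    """Jitter-free subcutaneous injection with known tissue parameters."""
    return simulate_injection(
        spring, tissue_truth, geom=geom, fluid=fluid,
        dose=240 * UL, jitter_sd=0.0, seed=2,
    )


@pytest.fixture(scope="session")
def calibrated_spring(air_pair, geom, fluid):
    return calibrate_spring([inj.flow for inj in air_pair], geom, fluid)
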