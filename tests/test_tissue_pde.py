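import numpy as np
import pytest

from penpress.errors import InvalidInputError
from penpress.tissue_pde import (
    PressureSolution,
    RadialGrid,
    TissueParams,
    darcy_velocity,
    depot_radius,
    solve_pressure,
    steady_state_pressure,
)
from penpress.units import ATM, MM, UL_PER_S


@pytest.fixture(scope="module")
def params():
    return TissueParams(k=1e-10, K=1e5, phi0=0.01)


@pytest.fixture(scope="module")
def grid():
    return RadialGrid(r_inner=0.1 * MM, r_outer=50 * MM, n_cells=200)


@pytest.fixture(scope="module")
def steady_solution(params, grid, fluid):
    """Constant 100 µL/s run to a late time (linearised mobility)."""
    t = np.linspace(0, 60, 31)
    return solve_pressure(params, 100 * UL_PER_S, fluid, grid, t, linearized=True)


@pytest.fixture(scope="module")
def transient_solution(params, grid, fluid):
    t = np.linspace(0, 2, 41)
    return solve_pressure(params, 100 * UL_PER_S, fluid, grid, t)


class TestEquilibriumAndValidation:
    def test_zero_flow_stays_at_rest(self, params, grid, fluid):
        sol = solve_pressure(params, 0.0, fluid, grid, np.linspace(0, 1, 5))
        assert np.allclose(sol.p, params.p0)
        assert np.allclose(sol.p_tip, params.p0)

    def test_t_eval_must_start_at_zero(self, params, grid, fluid):
        with pytest.raises(InvalidInputError):
            solve_pressure(params, 0.0, fluid, grid, np.array([0.5, 1.0]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            TissueParams(k=-1e-10, K=1e5)
        with pytest.raises(InvalidInputError):
            TissueParams(k=1e-10, K=1e5, phi0=1.5)
        with pytest.raises(InvalidInputError):
            RadialGrid(r_inner=1e-3, r_outer=5e-3)  # < 100 x r_inner


class TestSteadyState:
    def test_matches_closed_form_beyond_2_r_inner(self, steady_solution, params, grid, fluid):
        oracle = steady_state_pressure(params, 100 * UL_PER_S, fluid, steady_solution.r)
        mask = steady_solution.r >= 2 * grid.r_inner
        rel = np.abs(steady_solution.p[-1][mask] - oracle[mask]) / oracle[mask]
        assert rel.max() < 5e-3

    def test_closed_form_values(self, params, fluid):
        # Q µ / (4π k φ0 r): 1e-7·1e-3/(4π·1e-10·0.01·r)
        over = steady_state_pressure(params, 100 * UL_PER_S, fluid, 5 * MM) - params.p0
        assert over == pytest.approx(1.59e3, rel=1e-2)
        over = steady_state_pressure(params, 100 * UL_PER_S, fluid, 0.1 * MM) - params.p0
        assert over == pytest.approx(7.96e4, rel=1e-2)

    def test_far_field_limit(self, params, fluid):
        assert steady_state_pressure(params, 100 * UL_PER_S, fluid, 1e6) == pytest.approx(
            params.p0
        )


class TestConservationAndMonotonicity:
    def test_mass_balance_closes(self, transient_solution):
        assert abs(transient_solution.diagnostics["mass_balance_residual"]) < 1e-2

    def test_pressure_monotone_in_radius_and_time(self, transient_solution):
        p = transient_solution.p
        assert np.all(np.diff(p[-1]) <= 1e-6)              # non-increasing outward
        assert np.all(np.diff(p[:, 0]) >= -1e-6)           # tip cell rises to steady

    def test_constitutive_law_links_phi_and_p(self, transient_solution, params):
        raw = params.phi(transient_solution.p)
        inside = (raw > 1e-6) & (raw < 1.0)
        assert np.allclose(transient_solution.phi[inside], raw[inside])

    def test_mobility_ratio_invariance(self, params, grid, fluid):
        # k and µ only enter through k/µ
        from penpress.device_model import FluidProps

        t = np.linspace(0, 1, 11)
        sol1 = solve_pressure(params, 100 * UL_PER_S, fluid, grid, t)
        params2 = TissueParams(k=3 * params.k, K=params.K, phi0=params.phi0, p0=params.p0)
        fluid2 = FluidProps(mu=3 * fluid.mu, rho=fluid.rho)
        sol2 = solve_pressure(params2, 100 * UL_PER_S, fluid2, grid, t)
        assert np.allclose(sol1.p, sol2.p, rtol=1e-6, atol=1e-3)

    def test_grid_convergence_of_tip_pressure(self, params, fluid):
        t = np.linspace(0, 1, 11)
        coarse = RadialGrid(r_inner=0.1 * MM, r_outer=50 * MM, n_cells=200)
        fine = RadialGrid(r_inner=0.1 * MM, r_outer=50 * MM, n_cells=400)
        p1 = solve_pressure(params, 100 * UL_PER_S, fluid, coarse, t, rtol=1e-6).p_tip[-1]
        p2 = solve_pressure(params, 100 * UL_PER_S, fluid, fine, t, rtol=1e-7).p_tip[-1]
        assert abs(p1 - p2) / (p2 - ATM) < 5e-3


class TestDarcyVelocity:
    def test_equilibrium_velocity_vanishes(self, params, grid, fluid):
        sol = solve_pressure(params, 0.0, fluid, grid, np.linspace(0, 1, 5))
        assert np.allclose(darcy_velocity(sol, fluid), 0.0)

    def test_steady_flux_conservation(self, steady_solution, params, fluid):
        u = darcy_velocity(steady_solution, fluid)[-1]
        flux = 4 * np.pi * steady_solution.r**2 * params.phi0 * u
        interior = (steady_solution.r > 3 * steady_solution.grid.r_inner) & (
            steady_solution.r < 10 * MM
        )
        assert np.allclose(flux[interior], 100 * UL_PER_S, rtol=0.02)

    def test_overpressure_drives_outward_flow(self, transient_solution, fluid):
        u = darcy_velocity(transient_solution, fluid)[-1]
        inner = transient_solution.r < 5 * MM
        assert np.all(u[inner] > 0)


class TestDepotRadius:
    @staticmethod
    def _analytic_inverse_r_solution(params, grid, fluid):
        """Hand-built PressureSolution with an exact 1/r over-pressure profile."""
        amp = 1e4 * grid.r_inner  # tip over-pressure 1e4 Pa
        r = grid.r
        p = params.p0 + amp / r
        t = np.array([0.0, 1.0])
        pp = np.vstack([p, p])
        return PressureSolution(
            t=t, r=r, p=pp, phi=np.clip(params.phi(pp), 1e-6, 1),
            p_tip=np.array([params.p0 + amp / grid.r_inner] * 2),
            params=params, grid=grid, Q_used=lambda x: np.zeros_like(x),
            diagnostics={},
        )

    def test_inverse_r_profile_gives_exactly_ten_r_inner(self, params, fluid):
        grid = RadialGrid(r_inner=0.1 * MM, r_outer=50 * MM, n_cells=300)
        sol = self._analytic_inverse_r_solution(params, grid, fluid)
        assert depot_radius(sol, 0.1) == pytest.approx(10 * grid.r_inner, rel=1e-9)

    def test_fraction_near_one_collapses_to_needle(self, params, fluid):
        grid = RadialGrid(r_inner=0.1 * MM, r_outer=50 * MM, n_cells=300)
        sol = self._analytic_inverse_r_solution(params, grid, fluid)
        assert depot_radius(sol, 0.999) <= grid.r[0]

    def test_no_overpressure_returns_needle_radius(self, params, grid, fluid):
        sol = solve_pressure(params, 0.0, fluid, grid, np.linspace(0, 1, 3))
        assert depot_radius(sol, 0.1) == grid.r_inner

    def test_representative_injection_localized_within_5mm(self, transient_solution):
        assert depot_radius(transient_solution, 0.1) <= 5 * MM
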