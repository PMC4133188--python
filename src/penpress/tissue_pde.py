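"""Spherically symmetric poro-elastic pressure evolution around the needle tip.

Model
-----
The subcutis is treated as a homogeneous, isotropic porous elastic medium.
The injected fluid occupies a local volume fraction (porosity) ``φ`` and
moves with the Darcy velocity ``u = −(k/μ) ∇p``.  Displacing tissue costs
pressure: for small deformations the over-pressure is proportional to the
porosity change,

    p − p0 = K (φ − φ0),

with ``K`` an effective bulk modulus and ``φ0`` the small background
porosity.  Mass continuity of the incompressible fluid then closes the
system into a single nonlinear diffusion equation for the pressure,

    ∂p/∂t = (K k / μ) (1/r²) ∂r ( r² φ ∂r p ),     φ = φ0 + (p − p0)/K,

on ``r ∈ [r_inner, r_outer]``.  The needle tip is an infinitesimal source:
mass cannot accumulate there, so the full flow rate crosses the sphere of
radius ``r_inner`` (taken equal to the needle radius), giving the flux
boundary condition

    ∂r p |_{r_inner} = − Q(t) μ / (4π r_inner² k φ),

while the far field stays at the undisturbed pressure, ``p(r_outer) = p0``
(assumed atmospheric).

Numerics
--------
Conservative finite volumes on a logarithmic radial grid; stiff implicit
time integration (LSODA with a banded Jacobian).  Cumulative injected volume
and far-field outflux are carried as extra ODE states so the global mass
balance is available as a solver diagnostic.  The linear pressure–porosity
law can drive ``φ`` above one near the needle at high pressure, where the
constitutive law is no longer meaningful; the mobility is clamped to
``φ ∈ (1e-6, 1]`` and clamping events are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from penpress.click_io import FlowSeries
from penpress.device_model import FluidProps
from penpress.errors import InvalidInputError, StiffnessFailureError
from penpress.units import ATM, MM, UL

log = logging.getLogger(__name__)

PHI_FLOOR = 1e-6


@dataclass(frozen=True)
class TissueParams:
    """Poro-elastic tissue parameters.

    k : permeability, m² (adipose tissue ~1e-11–1e-10)
    K : effective bulk modulus, Pa (~1e5)
    phi0 : background porosity, dimensionless (small, ~0.01)
    p0 : undisturbed tissue pressure, Pa, absolute (default atmospheric)
    """

    k: float
    K: float
    phi0: float = 0.01
    p0: float = ATM

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise InvalidInputError("permeability k must be positive")
        if not self.K > 0:
            raise InvalidInputError("bulk modulus K must be positive")
        if not 0 < self.phi0 < 1:
            raise InvalidInputError("phi0 must lie in (0, 1)")
        if not self.p0 > 0:
            raise InvalidInputError("p0 must be positive (absolute pressure)")

    def phi(self, p):
        """Porosity from pressure via the linear constitutive law (unclamped)."""
        return self.phi0 + (np.asarray(p, dtype=float) - self.p0) / self.K


@dataclass(frozen=True)
class RadialGrid:
    """Logarithmic finite-volume grid from the needle surface to the far field.

    ``faces`` are the n_cells+1 cell boundaries (log-spaced), ``r`` the cell
    centers (geometric means of adjacent faces).
    """

    r_inner: float = 66.5e-6
    r_outer: float = 50 * MM
    n_cells: int = 200
    faces: np.ndarray = field(init=False, repr=False)
    r: np.ndarray = field(init=False, repr=False)
    volumes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.r_inner > 0:
            raise InvalidInputError("r_inner must be positive")
        if self.r_outer < 100 * self.r_inner:
            raise InvalidInputError("r_outer must be at least 100 * r_inner")
        if self.n_cells < 10:
            raise InvalidInputError("need at least 10 cells")
        faces = np.geomspace(self.r_inner, self.r_outer, self.n_cells + 1)
        centers = np.sqrt(faces[:-1] * faces[1:])
        volumes = 4.0 * np.pi / 3.0 * np.diff(faces**3)
        object.__setattr__(self, "faces", faces)
        object.__setattr__(self, "r", centers)
        object.__setattr__(self, "volumes", volumes)


@dataclass
class PressureSolution:
    """Pressure/porosity fields on (t × r) plus the needle-tip pressure trace."""

    t: np.ndarray
    r: np.ndarray
    p: np.ndarray        # Pa, shape (nt, nr)
    phi: np.ndarray      # clamped porosity, same shape
    p_tip: np.ndarray    # Pa at r_inner, shape (nt,)
    params: TissueParams
    grid: RadialGrid
    Q_used: Callable[[np.ndarray], np.ndarray]
    diagnostics: dict

    def overpressure(self):
        """p − p0 on the (t × r) grid."""
        return self.p - self.params.p0

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (t_s, r_mm, p_Pa, phi)."""
        tt, rr = np.meshgrid(self.t, self.r, indexing="ij")
        return pd.DataFrame(
            {
                "t_s": tt.ravel(),
                "r_mm": rr.ravel() / MM,
                "p_Pa": self.p.ravel(),
                "phi": self.phi.ravel(),
            }
        )

    def tip_frame(self) -> pd.DataFrame:
        """Compact needle-tip trace (t_s, p_tip_Pa)."""
        return pd.DataFrame({"t_s": self.t, "p_tip_Pa": self.p_tip})


def _as_flow_callable(Q_of_t) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(Q_of_t, FlowSeries):
        return Q_of_t.interpolator()
    if callable(Q_of_t):
        return Q_of_t
    q = float(Q_of_t)

    def const(x):
        return np.full_like(np.asarray(x, dtype=float), q)

    return const


def _clamped_phi(p, params: TissueParams):
    return np.clip(params.phi(p), PHI_FLOOR, 1.0)


def tip_pressure_from_cell(
    p_cell: float, Q: float, params: TissueParams, grid: RadialGrid,
    fluid: FluidProps, linearized: bool = False,
) -> float:
    """Extrapolate pressure from the first cell center to the needle surface.

    Uses the flux boundary condition: between ``r_inner`` and the first cell
    center the gradient is ``∂r p = −Qμ/(4π r_inner² k φ)``.  With the
    nonlinear law ``φ = φ0 + (p − p0)/K`` evaluated at the tip this is a
    quadratic in the tip pressure; the root above the cell pressure is taken,
    and the mobility is clamped to [PHI_FLOOR, 1].
    """
    C = Q * fluid.mu * (grid.r[0] - grid.r_inner) / (4.0 * np.pi * grid.r_inner**2 * params.k)
    if C <= 0:
        return float(p_cell)
    if linearized:
        return float(p_cell + C / params.phi0)
    # (x − p_cell)(φ0 + (x − p0)/K) = C, x = tip pressure
    K, phi0, p0 = params.K, params.phi0, params.p0
    B = K * phi0 - p0 - p_cell
    Cq = -K * p_cell * phi0 + p_cell * p0 - C * K
    disc = B * B - 4.0 * Cq
    x = 0.5 * (-B + np.sqrt(max(disc, 0.0)))
    phi_tip = params.phi(x)
    if phi_tip > 1.0:
        x = p_cell + C
    elif phi_tip < PHI_FLOOR:
        x = p_cell + C / PHI_FLOOR
    return float(x)


def solve_pressure(
    params: TissueParams,
    Q_of_t,
    fluid: FluidProps,
    grid: RadialGrid | None = None,
    t_eval: np.ndarray | None = None,
    *,
    linearized: bool = False,
    rtol: float = 1e-6,
    method: str = "LSODA",
) -> PressureSolution:
    """Integrate the poro-elastic pressure equation.

    Parameters
    ----------
    params
        Tissue parameters (k, K, φ0, p0).
    Q_of_t
        Boundary flow rate: a :class:`FlowSeries` (linear interpolation
        between click-interval midpoints, constant beyond the ends), a
        callable ``Q(t)`` in m³/s, or a constant.
    fluid
        Injected-fluid properties (only μ enters; k and μ appear solely as
        the mobility ratio k/μ).
    grid
        Radial finite-volume grid; default 200 log-spaced cells from the
        needle radius to 50 mm.
    t_eval
        Strictly increasing output times starting at 0 (initial state
        ``p ≡ p0``).
    linearized
        If True, use the background porosity ``φ0`` as the mobility weight
        everywhere (small-amplitude limit) instead of the pressure-dependent
        ``φ``; the equation becomes linear diffusion with
        ``D = K k φ0 / μ``.

    Returns
    -------
    PressureSolution
        With diagnostics ``mass_balance_residual`` (relative to injected
        volume), ``clamp_events`` and the raw solver report.
    """
    if grid is None:
        grid = RadialGrid()
    if t_eval is None:
        raise InvalidInputError("t_eval is required")
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[0] != 0 or np.any(np.diff(t_eval) <= 0):
        raise InvalidInputError("t_eval must start at 0 and be strictly increasing")

    Q = _as_flow_callable(Q_of_t)
    n = grid.n_cells
    rf = grid.faces
    rc = grid.r
    vol = grid.volumes
    area = 4.0 * np.pi * rf**2          # face areas
    inv_dr = 1.0 / np.diff(rc)          # interior face center-to-center
    inv_dr_out = 1.0 / (rf[-1] - rc[-1])
    mob = params.k / fluid.mu
    K, phi0, p0 = params.K, params.phi0, params.p0

    def rhs(t, y):
        p = y[:n]
        if linearized:
            phi_face_int = phi0
            phi_face_out = phi0
        else:
            phi = np.clip(phi0 + (p - p0) / K, PHI_FLOOR, 1.0)
            phi_face_int = 0.5 * (phi[:-1] + phi[1:])
            phi_face_out = 0.5 * (phi[-1] + phi0)
        q_in = float(np.asarray(Q(t)))
        # outward volumetric fluxes through faces
        flux_int = area[1:-1] * phi_face_int * mob * (p[:-1] - p[1:]) * inv_dr
        flux_out = area[-1] * phi_face_out * mob * (p[-1] - p0) * inv_dr_out
        dp = np.empty(n + 2)
        net = np.empty(n)
        net[0] = q_in - flux_int[0]
        net[1:-1] = flux_int[:-1] - flux_int[1:]
        net[-1] = flux_int[-1] - flux_out
        dp[:n] = K * net / vol
        dp[n] = flux_out   # cumulative far-field outflux
        dp[n + 1] = q_in   # cumulative injected volume
        return dp

    y0 = np.concatenate([np.full(n, p0), [0.0, 0.0]])
    atol = np.concatenate([np.full(n, 1e-3), [1e-16, 1e-16]])
    sol = solve_ivp(
        rhs,
        (t_eval[0], t_eval[-1]),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        lband=1,
        uband=1,
    )
    if not sol.success:
        raise StiffnessFailureError(f"pressure solver failed: {sol.message}")

    p = sol.y[:n].T                      # (nt, nr)
    phi_raw = params.phi(p)
    if np.any(phi_raw <= 0):
        raise StiffnessFailureError(
            "porosity became non-positive; constitutive law invalid at these parameters"
        )
    clamp_events = int(np.count_nonzero(phi_raw > 1.0) + np.count_nonzero(phi_raw < PHI_FLOOR))
    if clamp_events:
        log.info("porosity clamped at %d grid-time points", clamp_events)
    phi = np.clip(phi_raw, PHI_FLOOR, 1.0)

    q_eval = np.asarray(Q(sol.t), dtype=float)
    if q_eval.ndim == 0:
        q_eval = np.full_like(sol.t, float(q_eval))
    p_tip = np.array(
        [
            tip_pressure_from_cell(p[i, 0], q_eval[i], params, grid, fluid, linearized)
            for i in range(sol.t.size)
        ]
    )

    outflux = sol.y[n, -1]
    injected = sol.y[n + 1, -1]
    stored = float(np.sum((phi[-1] - phi0) * vol))
    denom = max(injected, UL * 1e-3)
    residual = (stored + outflux - injected) / denom
    diagnostics = {
        "mass_balance_residual": float(residual),
        "injected_volume": float(injected),
        "stored_volume": stored,
        "outflux_volume": float(outflux),
        "clamp_events": clamp_events,
        "solver_message": sol.message,
        "n_rhs_evaluations": int(sol.nfev),
    }
    return PressureSolution(
        t=sol.t, r=rc.copy(), p=p, phi=phi, p_tip=p_tip,
        params=params, grid=grid, Q_used=Q, diagnostics=diagnostics,
    )


def steady_state_pressure(params: TissueParams, Q, fluid: FluidProps, r):
    """Closed-form steady pressure in the small-amplitude limit (φ ≈ φ0).

    Constant flux through every sphere gives ``p(r) = p0 + Q μ / (4π k φ0 r)``.
    Serves as an analytic oracle for the linearised solver mode and as the
    far-field approximation of the nonlinear solution.
    """
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise InvalidInputError("Q must be non-negative")
    r = np.asarray(r, dtype=float)
    out = params.p0 + Q * fluid.mu / (4.0 * np.pi * params.k * params.phi0 * r)
    return float(out) if out.ndim == 0 else out


def darcy_velocity(solution: PressureSolution, fluid: FluidProps) -> np.ndarray:
    """Radial Darcy velocity ``u_r = −(k/μ) ∂r p`` on the (t × r) grid."""
    dp_dr = np.gradient(solution.p, solution.r, axis=1)
    return -(solution.params.k / fluid.mu) * dp_dr


def depot_radius(solution: PressureSolution, fraction: float = 0.1) -> float:
    """Radius of the over-pressurised region at the final time.

    Returns the largest radius at which the over-pressure ``p − p0`` still
    reaches ``fraction`` of its value at the needle surface.  The crossing is
    located by interpolation in log(r) vs log(over-pressure), which is exact
    for the 1/r quasi-steady profile.  If there is no over-pressure the
    needle radius is returned.
    """
    if not 0 < fraction < 1:
        raise InvalidInputError("fraction must lie in (0, 1)")
    p0 = solution.params.p0
    tip = solution.p_tip[-1] - p0
    if tip <= 0:
        return float(solution.grid.r_inner)
    radii = np.concatenate([[solution.grid.r_inner], solution.r])
    over = np.concatenate([[tip], solution.p[-1] - p0])
    target = fraction * tip
    pos = over > 0
    if over[pos][-1] >= target and pos[-1]:
        return float(radii[-1])
    # outermost index still at/above target
    above = np.flatnonzero(pos & (over >= target))
    if above.size == 0:
        return float(solution.grid.r_inner)
    i = above[-1]
    if i == radii.size - 1 or over[i + 1] <= 0:
        return float(radii[i])
    lr = np.log(radii[i : i + 2])
    lo = np.log(over[i : i + 2])
    f = (np.log(target) - lo[0]) / (lo[1] - lo[0])
    return float(np.exp(lr[0] + f * (lr[1] - lr[0])))
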