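"""Injection-device pressure balance and calibration.

The pen drives a piston of cross-section ``π r_s²`` with a torsion-spring
force ``F`` that depends only on the piston position, i.e. on the delivered
volume ``V`` (``d = V / (π r_s²)``).  Neglecting the viscous drop inside the
wide syringe bore, the absolute pressure at the needle outlet is

    p2 = F / (π r_s²) − Δp_needle(Q)

with the needle drop the sum of the fully developed Poiseuille term and a
kinetic/entry term,

    Δp_needle(Q) = 8 μ L_n Q / (π r_n⁴) + α ρ Q² / (2 π² r_n⁴).

Injections in air (p2 = atmospheric) calibrate the spring curve ``F(V)``;
with ``F(V)`` known, a subcutaneous injection's flow rate yields the tissue
pressure at the needle tip.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression

from penpress.click_io import FlowSeries
from penpress.errors import InvalidInputError
from penpress.units import ATM

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeviceGeometry:
    """Pen and needle geometry (SI units).

    Defaults describe a 3 mL pen cartridge with a 6 mm 31G needle:
    syringe inner radius 4.75 mm, needle inner radius 66.5 µm.
    ``alpha_kinetic`` is the dimensionless coefficient on the kinetic/entry
    pressure term; 2 corresponds to the kinetic-energy flux of a parabolic
    velocity profile.
    """

    r_s: float = 4.75e-3
    r_n: float = 66.5e-6
    L_n: float = 6.0e-3
    alpha_kinetic: float = 2.0

    def __post_init__(self) -> None:
        if not (self.r_s > 0 and self.r_n > 0 and self.L_n > 0):
            raise InvalidInputError("all device lengths must be positive")
        if self.r_n >= self.r_s:
            raise InvalidInputError("needle radius must be smaller than syringe radius")
        if self.alpha_kinetic < 0:
            raise InvalidInputError("alpha_kinetic must be non-negative")

    @property
    def piston_area(self) -> float:
        return float(np.pi * self.r_s**2)


@dataclass(frozen=True)
class FluidProps:
    """Injected-fluid properties; defaults are water at room temperature."""

    mu: float = 1.0e-3  # Pa·s
    rho: float = 1.0e3  # kg/m³

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.rho > 0):
            raise InvalidInputError("mu and rho must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity m²/s."""
        return self.mu / self.rho


class SpringCurve:
    """Calibrated spring force as a function of delivered volume.

    Linear interpolation between knots; flat extrapolation outside the
    calibrated range (with a warning, since extrapolated forces are not
    backed by data).  After calibration the knot forces are non-increasing:
    the spring untwists as the dose is delivered.
    """

    def __init__(self, V_knots: np.ndarray, F_knots: np.ndarray):
        V = np.asarray(V_knots, dtype=float)
        F = np.asarray(F_knots, dtype=float)
        if V.ndim != 1 or V.shape != F.shape or V.size < 1:
            raise InvalidInputError("V_knots and F_knots must be equal-length 1-D arrays")
        if V.size >= 2 and not np.all(np.diff(V) > 0):
            raise InvalidInputError("V_knots must be strictly increasing")
        if np.any(F < 0):
            raise InvalidInputError("spring force must be non-negative")
        self.V_knots = V
        self.F_knots = F

    def __call__(self, V) -> np.ndarray:
        """Spring force (N) at delivered volume ``V`` (m³)."""
        V = np.asarray(V, dtype=float)
        lo, hi = self.V_knots[0], self.V_knots[-1]
        tol = 1e-9 * max(hi - lo, hi)
        if np.any(V < lo - tol) or np.any(V > hi + tol):
            warnings.warn(
                "spring curve evaluated outside calibrated volume range; "
                "using flat extrapolation",
                stacklevel=2,
            )
        return np.interp(V, self.V_knots, self.F_knots)

    def covers(self, V) -> bool:
        V = np.asarray(V, dtype=float)
        tol = 1e-9 * max(self.V_knots[-1] - self.V_knots[0], self.V_knots[-1])
        return bool(
            V.min() >= self.V_knots[0] - tol and V.max() <= self.V_knots[-1] + tol
        )

    @classmethod
    def linear(cls, F0: float, slope: float, V_max: float, n_knots: int = 2) -> "SpringCurve":
        """Convenience constructor ``F(V) = F0 − slope · V`` on [0, V_max]."""
        V = np.linspace(0.0, V_max, max(n_knots, 2))
        return cls(V, np.maximum(F0 - slope * V, 0.0))


def needle_pressure_drop(Q, geom: DeviceGeometry, fluid: FluidProps):
    """Pressure drop along the needle at flow rate ``Q`` (m³/s) → Pa.

    Poiseuille term plus kinetic/entry term; strictly increasing in Q and
    scaling as ``r_n⁻⁴``.
    """
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise InvalidInputError("flow rate must be non-negative")
    r4 = geom.r_n**4
    viscous = 8.0 * fluid.mu * geom.L_n * Q / (np.pi * r4)
    kinetic = geom.alpha_kinetic * fluid.rho * Q**2 / (2.0 * np.pi**2 * r4)
    out = viscous + kinetic
    return float(out) if out.ndim == 0 else out


def syringe_pressure_drop(Q, geom: DeviceGeometry, fluid: FluidProps):
    """Poiseuille drop along the syringe bore (upper estimate), for diagnostics.

    The bore is treated as a pipe of radius ``r_s`` and length equal to the
    needle length scale of the cartridge (taken as 5 cm); the point of the
    diagnostic is only the ``(r_n/r_s)⁴`` smallness, so the exact length is
    immaterial.
    """
    L_syringe = 0.05
    Q = np.asarray(Q, dtype=float)
    return 8.0 * fluid.mu * L_syringe * Q / (np.pi * geom.r_s**4)


def needle_to_syringe_drop_ratio(Q, geom: DeviceGeometry, fluid: FluidProps) -> float:
    """Diagnostic: needle drop / syringe-bore Poiseuille drop (should be ≫ 1)."""
    return float(
        needle_pressure_drop(Q, geom, fluid) / syringe_pressure_drop(Q, geom, fluid)
    )


def outlet_pressure(F, Q, geom: DeviceGeometry, fluid: FluidProps):
    """Absolute pressure at the needle outlet given spring force and flow rate.

    ``p2 = F/(π r_s²) − Δp_needle(Q)``.  The caller is responsible for the
    pressure reference: if ``F`` was calibrated against absolute outlet
    pressure (see :func:`calibrate_spring`), the result is absolute.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise InvalidInputError("spring force must be non-negative")
    out = F / geom.piston_area - needle_pressure_drop(Q, geom, fluid)
    return float(out) if out.ndim == 0 else out


def spring_force_from_outlet(p2, Q, geom: DeviceGeometry, fluid: FluidProps):
    """Spring force implied by outlet pressure and flow rate (inverse of
    :func:`outlet_pressure`).

    A negative result is non-physical for a pushing spring; it is returned
    unchanged but flagged with a warning so calibration problems surface.
    """
    p2 = np.asarray(p2, dtype=float)
    out = geom.piston_area * (p2 + needle_pressure_drop(Q, geom, fluid))
    if np.any(out < 0):
        warnings.warn("non-physical negative spring force from calibration", stacklevel=2)
    return float(out) if out.ndim == 0 else out


def calibrate_spring(
    air_flows: list[FlowSeries] | FlowSeries,
    geom: DeviceGeometry,
    fluid: FluidProps,
    p_ref: float = ATM,
    grid_step: float | None = None,
) -> SpringCurve:
    """Estimate the spring curve ``F(V)`` from injections in air.

    In air the outlet pressure equals the known reference pressure, so each
    flow interval gives one point ``F(V_mid) = π r_s² (p_ref + Δp_needle(Q))``.
    Multiple reference series (e.g. one before and one after the tissue
    injection) are pooled on a shared volume grid by averaging, and the
    pooled curve is projected onto the non-increasing cone (the spring only
    untwists), which also absorbs single-interval outliers.

    Parameters
    ----------
    air_flows
        One or more air-reference :class:`FlowSeries` from the same pen.
    p_ref
        Absolute outlet pressure during the air injections (default 1 atm).
    grid_step
        Spacing of the shared volume grid; defaults to the volume per click.
    """
    if isinstance(air_flows, FlowSeries):
        air_flows = [air_flows]
    if not air_flows:
        raise InvalidInputError("at least one air flow series is required")

    step = grid_step if grid_step is not None else air_flows[0].volume_per_click
    v_lo = min(f.V_mid.min() for f in air_flows)
    v_hi = max(f.V_mid.max() for f in air_flows)
    grid = v_lo + step * np.arange(int(np.floor((v_hi - v_lo) / step + 0.5)) + 1)
    if grid.size < 2:
        grid = np.array([v_lo, v_hi]) if v_hi > v_lo else np.array([v_lo])
    # snap knots onto coincident data points so the calibration reproduces
    # them exactly (a knot one ulp off a V_mid would mix adjacent intervals)
    all_v = np.unique(np.concatenate([f.V_mid for f in air_flows]))
    idx = np.searchsorted(all_v, grid)
    for j, i in enumerate(idx):
        for cand in (i - 1, i):
            if 0 <= cand < all_v.size and abs(all_v[cand] - grid[j]) < 1e-9 * step:
                grid[j] = all_v[cand]

    stack = np.full((len(air_flows), grid.size), np.nan)
    for j, flow in enumerate(air_flows):
        F = spring_force_from_outlet(p_ref, flow.Q, geom, fluid)
        inside = (grid >= flow.V_mid.min()) & (grid <= flow.V_mid.max())
        stack[j, inside] = np.interp(grid[inside], flow.V_mid, F)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pooled = np.nanmean(stack, axis=0)
    ok = np.isfinite(pooled)
    grid, pooled = grid[ok], pooled[ok]

    if grid.size >= 2:
        # non-increasing isotonic projection (PAVA)
        pooled = isotonic_regression(pooled, increasing=False).x
    return SpringCurve(grid, np.maximum(pooled, 0.0))


def needle_radius_from_flow(
    delta_p: float,
    Q: float,
    L_n: float,
    fluid: FluidProps,
    alpha_kinetic: float = 2.0,
) -> float:
    """Needle inner radius from a measured (Δp, Q) pair.

    Closed-form inverse of :func:`needle_pressure_drop`: both terms scale as
    ``r_n⁻⁴``, so

        r_n = [ (8 μ L_n Q / π + α ρ Q² / (2π²)) / Δp ]^(1/4).

    This is how each needle is calibrated after use, by driving a known
    pressure across it and measuring the flow.
    """
    if not (delta_p > 0 and Q > 0):
        raise InvalidInputError("delta_p and Q must be positive")
    num = 8.0 * fluid.mu * L_n * Q / np.pi + alpha_kinetic * fluid.rho * Q**2 / (
        2.0 * np.pi**2
    )
    return float((num / delta_p) ** 0.25)
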