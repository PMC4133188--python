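"""Least-squares estimation of tissue permeability and bulk modulus.

The device-derived needle-outlet pressure of a subcutaneous injection is the
tissue pressure at the needle tip.  The poro-elastic model predicts the same
quantity when driven with the measured flow rate as its boundary condition,
so the free parameters (k, K) are found by minimising

    SSE(k, K) = Σ_i [ p_tip_model(t_i; k, K) − p2_measured(t_i) ]²

over log10(k), log10(K).  Log-space absorbs the multi-decade prior
uncertainty; the optimiser is a bounded Nelder-Mead simplex, robust to the
mild noise the PDE solve injects into the objective.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from penpress.click_io import FlowSeries
from penpress.counter_pressure import PressureSeries
from penpress.device_model import DeviceGeometry, FluidProps
from penpress.errors import InvalidInputError, PenpressError
from penpress.tissue_pde import RadialGrid, TissueParams, solve_pressure
from penpress.units import ATM, MM

log = logging.getLogger(__name__)

DEFAULT_BOUNDS = ((1e-14, 1e-8), (1e3, 1e8))
DEFAULT_INIT = (1e-11, 1e5)


@dataclass
class FitResult:
    """Outcome of a (k, K) fit."""

    k_hat: float
    K_hat: float
    sse: float
    n_points: int
    converged: bool
    trace: list = field(default_factory=list)
    bounds_hit: dict = field(default_factory=dict)
    params: TissueParams | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "k_m2": self.k_hat,
                "K_Pa": self.K_hat,
                "sse_Pa2": self.sse,
                "n_points": self.n_points,
                "converged": self.converged,
                "bounds_hit": self.bounds_hit,
                "n_evaluations": len(self.trace),
            },
            indent=2,
        )


def _model_tip_pressure(
    k: float,
    K: float,
    measured: PressureSeries,
    Q_of_t: FlowSeries,
    grid: RadialGrid,
    fluid: FluidProps,
    phi0: float,
    p0: float,
    rtol: float,
) -> np.ndarray:
    params = TissueParams(k=k, K=K, phi0=phi0, p0=p0)
    t_end = float(measured.t_mid[-1])
    n_out = max(len(measured), 20)
    t_eval = np.unique(np.concatenate([[0.0], np.linspace(0, t_end, n_out + 1)[1:], measured.t_mid]))
    sol = solve_pressure(params, Q_of_t, fluid, grid, t_eval, rtol=rtol)
    return np.interp(measured.t_mid, sol.t, sol.p_tip)


def fit_tissue_params(
    measured: PressureSeries,
    Q_of_t: FlowSeries,
    geom: DeviceGeometry,
    fluid: FluidProps,
    phi0: float = 0.01,
    p0: float = ATM,
    init: tuple[float, float] = DEFAULT_INIT,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    grid: RadialGrid | None = None,
    search_rtol: float = 1e-5,
    polish_rtol: float = 1e-6,
    maxiter: int = 120,
) -> FitResult:
    """Fit permeability ``k`` and bulk modulus ``K`` to a measured tip-pressure series.

    Parameters
    ----------
    measured
        Device-derived needle-outlet pressure series of the tissue injection.
    Q_of_t
        The tissue flow series, used as the PDE boundary condition.
    phi0, p0
        Background porosity and undisturbed pressure, held fixed.
    init, bounds
        Initial guess and box bounds for (k, K); optimisation runs in
        log10 space.
    grid
        PDE grid; defaults to 120 log-spaced cells from the needle radius to
        50 mm, a resolution at which the tip pressure is grid-converged well
        below measurement noise.
    search_rtol, polish_rtol
        PDE solver tolerance during the search and for the final evaluation.

    Notes
    -----
    PDE failures at trial parameters are absorbed into a large penalty so a
    stiff corner of parameter space cannot crash the fit.  If the optimum
    sits on a bound (e.g. a zero counter-pressure series pushes ``k`` to its
    upper bound because the tissue is indistinguishable from free outflow),
    the corresponding ``bounds_hit`` flag is set.
    """
    if len(measured) != len(Q_of_t) or not np.allclose(measured.t_mid, Q_of_t.t_mid):
        raise InvalidInputError("measured series and flow series must share the interval grid")
    (k_lo, k_hi), (K_lo, K_hi) = bounds
    if not (k_lo < init[0] < k_hi and K_lo < init[1] < K_hi):
        raise InvalidInputError("init must lie strictly inside bounds")
    if grid is None:
        grid = RadialGrid(r_inner=geom.r_n, r_outer=50 * MM, n_cells=120)

    target = measured.p2
    penalty = 1e4 * float(np.sum((target - p0) ** 2) + 1e6)
    trace: list[tuple[float, float, float]] = []

    def objective(theta):
        k = 10.0 ** theta[0]
        K = 10.0 ** theta[1]
        try:
            tip = _model_tip_pressure(
                k, K, measured, Q_of_t, grid, fluid, phi0, p0, search_rtol
            )
            sse = float(np.sum((tip - target) ** 2))
        except PenpressError as exc:
            log.debug("penalised solver failure at k=%.3g K=%.3g: %s", k, K, exc)
            sse = penalty
        trace.append((k, K, sse))
        return sse

    x0 = np.log10(init)
    log_bounds = (np.log10([k_lo, k_hi]), np.log10([K_lo, K_hi]))
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=list(zip(*log_bounds)),
        options={
            "maxiter": maxiter,
            "xatol": 5e-3,   # ~1% in the parameters
            "fatol": 1e-12,
            "initial_simplex": x0 + np.array([[0, 0], [0.5, 0], [0, 0.5]]),
        },
    )
    k_hat, K_hat = 10.0 ** res.x

    try:
        tip = _model_tip_pressure(
            k_hat, K_hat, measured, Q_of_t, grid, fluid, phi0, p0, polish_rtol
        )
        sse = float(np.sum((tip - target) ** 2))
    except PenpressError:
        sse = penalty

    tol = 1e-2  # within 1% of a log-bound counts as "on the bound"
    bounds_hit = {
        "k_low": bool(res.x[0] - np.log10(k_lo) < tol),
        "k_high": bool(np.log10(k_hi) - res.x[0] < tol),
        "K_low": bool(res.x[1] - np.log10(K_lo) < tol),
        "K_high": bool(np.log10(K_hi) - res.x[1] < tol),
    }
    return FitResult(
        k_hat=float(k_hat),
        K_hat=float(K_hat),
        sse=sse,
        n_points=len(measured),
        converged=bool(res.success),
        trace=trace,
        bounds_hit=bounds_hit,
        params=TissueParams(k=float(k_hat), K=float(K_hat), phi0=phi0, p0=p0),
    )


def predicted_tip_pressure(
    result: FitResult,
    measured: PressureSeries,
    Q_of_t: FlowSeries,
    geom: DeviceGeometry,
    fluid: FluidProps,
    grid: RadialGrid | None = None,
    rtol: float = 1e-6,
) -> np.ndarray:
    """Model tip pressure at the measured times for a fitted result (for overlays)."""
    if grid is None:
        grid = RadialGrid(r_inner=geom.r_n, r_outer=50 * MM, n_cells=120)
    assert result.params is not None
    return _model_tip_pressure(
        result.params.k, result.params.K, measured, Q_of_t, grid, fluid,
        result.params.phi0, result.params.p0, rtol,
    )


def plot_fit_overlay(result, measured, Q_of_t, geom, fluid, ax=None):
    """Measured vs model needle-tip pressure (mbar over reference)."""
    import matplotlib.pyplot as plt

    from penpress.units import MBAR

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    model = predicted_tip_pressure(result, measured, Q_of_t, geom, fluid)
    ax.plot(measured.t_mid, (measured.p2 - measured.p_ref) / MBAR, "k-", label="measured")
    ax.plot(measured.t_mid, (model - measured.p_ref) / MBAR, "r--", label="model fit")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("counter pressure [mbar]")
    ax.legend(frameon=False)
    return ax
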