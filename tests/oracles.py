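"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's finite-volume machinery: the linear
diffusion reference works in the log-radius coordinate with uniform central
differences and a dense implicit integrator, so agreement with the package
solver is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def linear_diffusion_reference(
    D: float,
    Q: float,
    mu: float,
    k: float,
    phi0: float,
    p0: float,
    r_inner: float,
    r_outer: float,
    t_eval: np.ndarray,
    n_nodes: int = 300,
):
    """Small-amplitude spherical pressure diffusion, solved independently.

    Solves ``∂p/∂t = D (p'' + 2p'/r)`` with flux condition
    ``p'(r_inner) = −Qμ/(4π r_inner² k φ0)`` and ``p(r_outer) = p0``.
    Written in ``x = ln r`` (uniform grid): ``∂p/∂t = D e^{-2x} (p_xx + p_x)``.
    The inner node is eliminated through a second-order one-sided stencil.

    Returns (r_nodes, p) with p of shape (len(t_eval), n_nodes).
    """
    x = np.linspace(np.log(r_inner), np.log(r_outer), n_nodes)
    h = x[1] - x[0]
    r = np.exp(x)
    grad_inner = -Q * mu / (4.0 * np.pi * r_inner**2 * k * phi0)  # dp/dr at r_inner
    px0 = r_inner * grad_inner                                    # dp/dx at x_0

    def boundary_value(p1, p2):
        # (-3 p0 + 4 p1 - p2) / (2h) = px0
        return (4.0 * p1 - p2 - 2.0 * h * px0) / 3.0

    inner = slice(1, n_nodes - 1)
    coef = D * np.exp(-2.0 * x[inner])

    def rhs(t, y):
        p = np.empty(n_nodes)
        p[1:-1] = y
        p[-1] = p0
        p[0] = boundary_value(p[1], p[2])
        pxx = (p[:-2] - 2.0 * p[1:-1] + p[2:]) / h**2
        px = (p[2:] - p[:-2]) / (2.0 * h)
        return coef * (pxx + px)

    y0 = np.full(n_nodes - 2, p0)
    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), y0, method="BDF",
                    t_eval=t_eval, rtol=1e-8, atol=1e-8)
    assert sol.success, sol.message
    p = np.empty((t_eval.size, n_nodes))
    p[:, 1:-1] = sol.y.T
    p[:, -1] = p0
    p[:, 0] = boundary_value(p[:, 1], p[:, 2])
    return r, p


def scalar_air_balance_flow(F, geom, fluid, p_ref, n_iter=200):
    """Solve F/(π r_s²) = p_ref + Δp(Q) for Q by plain bisection.

    Independent of scipy root finding and of the package's flow solver.
    """
    area = np.pi * geom.r_s**2
    target = F / area - p_ref

    def drop(q):
        r4 = geom.r_n**4
        return (8 * fluid.mu * geom.L_n * q / (np.pi * r4)
                + geom.alpha_kinetic * fluid.rho * q**2 / (2 * np.pi**2 * r4))

    if target <= 0:
        return 0.0
    lo, hi = 0.0, 1.0
    while drop(hi) < target:
        hi *= 2
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if drop(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
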