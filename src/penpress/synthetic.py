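"""Forward simulation of the coupled device–tissue system.

No patient recordings are published for this kind of measurement, so every
pipeline stage is exercised on synthetic injections with known ground truth.
The instantaneous flow rate Q solves the scalar device balance

    F(V) / (π r_s²) = p_tip(Q) + Δp_needle(Q)

with ``p_tip`` the needle-tip tissue pressure from the poro-elastic model
(or the reference pressure for air injections).  The delivered volume V and
the tissue pressure field are integrated as one coupled stiff ODE system:
Q is recomputed from the balance inside every right-hand-side evaluation,
so the device–tissue feedback is resolved to solver tolerance rather than
split into alternating steps (the near-needle cells are far stiffer than
any reasonable splitting interval).  A click is emitted every
``volume_per_click`` of delivered volume — click times are roots of
``V(t) = m · volume_per_click`` on the dense ODE solution — and optional
Gaussian timing jitter models microphone/detection error.

Defaults emulate the study conditions: spring-driven air flows decelerating
from ~150 to ~80 µL/s over 1–3 s, doses of 180–480 µL in 10 µL clicks, a
visible flow drop when the same pen injects into tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from penpress.click_io import ClickTrain, FlowSeries, flow_from_clicks
from penpress.counter_pressure import PressureSeries
from penpress.device_model import (
    DeviceGeometry,
    FluidProps,
    SpringCurve,
    needle_pressure_drop,
    spring_force_from_outlet,
)
from penpress.errors import InvalidInputError
from penpress.tissue_pde import (
    PHI_FLOOR,
    RadialGrid,
    TissueParams,
    tip_pressure_from_cell,
)
from penpress.units import ATM, MM, UL, UL_PER_S, VOLUME_PER_CLICK


@dataclass
class SyntheticInjection:
    """One simulated injection with its ground truth.

    ``clicks``/``flow`` are the observables the real pipeline would see
    (click times include jitter); ``tip_pressure`` is the true needle-tip
    pressure sampled at the flow-interval midpoints; ``t_grid``/``Q_grid``/
    ``p_tip_grid`` are the continuous simulator traces.
    """

    truth: TissueParams | str
    spring_truth: SpringCurve
    clicks: ClickTrain
    flow: FlowSeries
    tip_pressure: PressureSeries
    seed: int | None
    stalled: bool
    t_grid: np.ndarray
    Q_grid: np.ndarray
    p_tip_grid: np.ndarray

    @property
    def is_air(self) -> bool:
        return isinstance(self.truth, str)


def _solve_flow(
    F: float,
    tip_at_Q: Callable[[float], float],
    geom: DeviceGeometry,
    fluid: FluidProps,
    q_max: float = 2000 * UL_PER_S,
) -> float:
    """Solve the scalar device balance for Q; returns 0 if the spring stalls."""
    area = geom.piston_area

    def g(Q):
        return F / area - needle_pressure_drop(Q, geom, fluid) - tip_at_Q(Q)

    if g(0.0) <= 0:
        return 0.0
    hi = 10 * UL_PER_S
    while g(hi) > 0:
        hi *= 2.0
        if hi > q_max:
            return q_max
    return brentq(g, 0.0, hi, xtol=1e-16, rtol=1e-12)


def simulate_injection(
    spring: SpringCurve,
    tissue: TissueParams | str,
    geom: DeviceGeometry | None = None,
    fluid: FluidProps | None = None,
    dose: float = 240 * UL,
    jitter_sd: float = 2e-3,
    seed: int | None = None,
    *,
    volume_per_click: float = VOLUME_PER_CLICK,
    p_ref: float = ATM,
    dt: float = 1e-3,
    grid: RadialGrid | None = None,
    subject_id: str = "synthetic",
    append_tail_drop: bool = False,
    max_time: float = 30.0,
) -> SyntheticInjection:
    """Simulate one injection of ``dose`` m³ through the device.

    Parameters
    ----------
    spring
        True spring curve; must cover [0, dose].
    tissue
        ``"air"`` for a reference injection at ``p_ref``, or the true
        :class:`TissueParams` for a subcutaneous injection.
    dose
        Total delivered volume; must be a positive multiple of
        ``volume_per_click``.
    jitter_sd
        SD of independent Gaussian jitter added to click times (s).
    append_tail_drop
        If True, two artificially slow trailing clicks are appended after
        the dose, mimicking the device's deliberate end-of-injection force
        drop, to exercise tail truncation downstream.

    Returns
    -------
    SyntheticInjection
        ``stalled`` is set (with a partial dose) if the spring force cannot
        overcome the tissue pressure.
    """
    geom = geom or DeviceGeometry()
    fluid = fluid or FluidProps()
    n_clicks = dose / volume_per_click
    if not (dose > 0 and abs(n_clicks - round(n_clicks)) < 1e-9):
        raise InvalidInputError("dose must be a positive multiple of volume_per_click")
    if not spring.covers([0.0, dose]):
        raise InvalidInputError("spring curve must cover [0, dose]")
    is_air = isinstance(tissue, str)
    if is_air and tissue != "air":
        raise InvalidInputError("tissue must be TissueParams or the string 'air'")

    if not is_air:
        grid = grid or RadialGrid(r_inner=geom.r_n, r_outer=50 * MM, n_cells=150)
    rng = np.random.default_rng(seed)
    v_max = float(spring.V_knots[-1])

    def spring_force(V: float) -> float:
        return float(spring(np.clip(V, 0.0, v_max)))

    if is_air:
        # scalar ODE dV/dt = Q(F(V))
        def rhs(t, y):
            Q = _solve_flow(spring_force(y[0]), lambda q: p_ref, geom, fluid)
            return [Q]

        y0 = [0.0]
        n_pde = 0
        solver_opts: dict = {}
    else:
        # coupled system: y = [V, p_1..p_n]; Q from the device balance at the
        # current tissue state.  V first keeps the Jacobian tridiagonal.
        n_pde = grid.n_cells
        rf, rc = grid.faces, grid.r
        area = 4.0 * np.pi * rf**2
        inv_dr = 1.0 / np.diff(rc)
        inv_dr_out = 1.0 / (rf[-1] - rc[-1])
        mob = tissue.k / fluid.mu
        K, phi0, p0t = tissue.K, tissue.phi0, tissue.p0
        vol = grid.volumes

        def flow_at(state_V: float, p_cell0: float) -> float:
            def tip(q):
                return tip_pressure_from_cell(p_cell0, q, tissue, grid, fluid)

            return _solve_flow(spring_force(state_V), tip, geom, fluid)

        def rhs(t, y):
            p = y[1:]
            Q = flow_at(y[0], p[0])
            phi = np.clip(phi0 + (p - p0t) / K, PHI_FLOOR, 1.0)
            flux_int = (
                area[1:-1] * 0.5 * (phi[:-1] + phi[1:]) * mob * (p[:-1] - p[1:]) * inv_dr
            )
            flux_out = area[-1] * 0.5 * (phi[-1] + phi0) * mob * (p[-1] - p0t) * inv_dr_out
            dp = np.empty(n_pde + 1)
            dp[0] = Q
            dp[1] = K * (Q - flux_int[0]) / vol[0]
            dp[2:-1] = K * (flux_int[:-1] - flux_int[1:]) / vol[1:-1]
            dp[-1] = K * (flux_int[-1] - flux_out) / vol[-1]
            return dp

        y0 = np.concatenate([[0.0], np.full(n_pde, tissue.p0)])
        solver_opts = {"lband": 1, "uband": 1}

    def dose_reached(t, y):
        return y[0] - dose

    dose_reached.terminal = True
    dose_reached.direction = 1.0

    from scipy.integrate import solve_ivp

    atol = np.concatenate([[1e-14], np.full(n_pde, 1e-3)]) if n_pde else 1e-14
    sol = solve_ivp(
        rhs, (0.0, max_time), y0, method="LSODA", events=[dose_reached],
        dense_output=True, rtol=1e-7, atol=atol, **solver_opts,
    )
    t_end = float(sol.t[-1])
    stalled = not (sol.t_events[0].size > 0)
    v_end = float(sol.y[0, -1])

    # continuous traces on a uniform grid
    t_grid = np.arange(0.0, t_end + 0.5 * dt, dt)
    t_grid[-1] = min(t_grid[-1], t_end)
    y_grid = sol.sol(t_grid)
    if is_air:
        Q_grid = np.array(
            [_solve_flow(spring_force(v), lambda q: p_ref, geom, fluid) for v in y_grid[0]]
        )
        p_tip_grid = np.full(t_grid.shape, p_ref)
    else:
        Q_grid = np.array([flow_at(v, pc) for v, pc in zip(y_grid[0], y_grid[1])])
        p_tip_grid = np.array(
            [
                tip_pressure_from_cell(pc, q, tissue, grid, fluid)
                for pc, q in zip(y_grid[1], Q_grid)
            ]
        )

    # click times: roots of V(t) = m * volume_per_click on the dense solution.
    # The terminal event leaves v_end within solver tolerance of the dose, so
    # a final target marginally above v_end is the completion instant itself.
    n_emitted = int(np.floor((v_end + 1e-6 * volume_per_click) / volume_per_click))
    click_times_l: list[float] = []
    t_lo = 0.0
    for m in range(1, n_emitted + 1):
        target = m * volume_per_click

        def crossing(x):
            return float(sol.sol(x)[0]) - target

        if crossing(t_end) <= 0:
            click_times_l.append(t_end)
        else:
            click_times_l.append(brentq(crossing, t_lo, t_end, xtol=1e-12))
        t_lo = click_times_l[-1]
    click_times = np.asarray(click_times_l)
    if append_tail_drop and click_times.size >= 2:
        last_gap = click_times[-1] - click_times[-2]
        extra = click_times[-1] + last_gap * 3.0 * np.arange(1, 3)
        click_times = np.concatenate([click_times, extra])
    if jitter_sd > 0 and click_times.size:
        click_times = click_times + rng.normal(0.0, jitter_sd, size=click_times.size)
        click_times = np.sort(click_times)
        # enforce strict monotonicity after jitter
        for i in range(1, click_times.size):
            if click_times[i] <= click_times[i - 1]:
                click_times[i] = click_times[i - 1] + 1e-6

    medium = "air" if is_air else "tissue"
    clicks = ClickTrain(click_times, volume_per_click, subject_id, medium)
    if clicks.n_clicks >= 2:
        flow = flow_from_clicks(clicks, truncate_tail=0)
    else:  # stalled before the second click: empty observable series
        flow = FlowSeries(
            np.empty(0), np.empty(0), np.empty(0), volume_per_click, subject_id, medium
        )
    tip_at_mid = (
        np.full(len(flow), p_ref)
        if is_air
        else np.interp(flow.t_mid, t_grid, p_tip_grid)
    )
    tip_pressure = PressureSeries(
        t_mid=flow.t_mid, V_mid=flow.V_mid, p2=tip_at_mid,
        p_ref=p_ref, subject_id=subject_id,
    )
    return SyntheticInjection(
        truth=tissue,
        spring_truth=spring,
        clicks=clicks,
        flow=flow,
        tip_pressure=tip_pressure,
        seed=seed,
        stalled=stalled,
        t_grid=t_grid,
        Q_grid=Q_grid,
        p_tip_grid=p_tip_grid,
    )


def default_spring_family(
    geom: DeviceGeometry | None = None,
    fluid: FluidProps | None = None,
    p_ref: float = ATM,
    q_start_range: tuple[float, float] = (140 * UL_PER_S, 160 * UL_PER_S),
    q_end_range: tuple[float, float] = (70 * UL_PER_S, 90 * UL_PER_S),
) -> Callable[[np.random.Generator, float], SpringCurve]:
    """Springs parameterised by their air-flow envelope.

    Rather than drawing forces directly, a spring is defined by the air flow
    rate it produces at the start (~150 µL/s) and end (~80 µL/s) of the dose;
    the corresponding forces follow from the device balance.  This pins the
    synthetic flow profiles to the decelerating shape real pens show,
    whatever the configured geometry.
    """
    geom = geom or DeviceGeometry()
    fluid = fluid or FluidProps()

    def family(rng: np.random.Generator, dose: float) -> SpringCurve:
        q0 = rng.uniform(*q_start_range)
        q1 = rng.uniform(*q_end_range)
        F0 = spring_force_from_outlet(p_ref, q0, geom, fluid)
        F1 = spring_force_from_outlet(p_ref, q1, geom, fluid)
        slope = (F0 - F1) / dose
        return SpringCurve.linear(F0, slope, V_max=1.1 * dose)

    return family


@dataclass
class CohortSubject:
    """Paired synthetic injections for one subject: two air references + one tissue."""

    subject_id: str
    truth: TissueParams
    spring: SpringCurve
    air_pre: SyntheticInjection
    air_post: SyntheticInjection
    tissue: SyntheticInjection


def make_cohort(
    n_subjects: int = 11,
    k_range: tuple[float, float] = (1e-11, 1e-10),
    K_range: tuple[float, float] = (3e4, 3e5),
    spring_family: Callable[[np.random.Generator, float], SpringCurve] | None = None,
    dose_range: tuple[float, float] = (180 * UL, 480 * UL),
    jitter_sd: float = 2e-3,
    seed: int | None = 0,
    *,
    geom: DeviceGeometry | None = None,
    fluid: FluidProps | None = None,
    volume_per_click: float = VOLUME_PER_CLICK,
    p_ref: float = ATM,
) -> list[CohortSubject]:
    """Simulate a cohort of subjects with log-uniform tissue parameters.

    Each subject gets one pen (one spring curve), a dose drawn uniformly
    from ``dose_range`` and rounded to the click volume, two air reference
    injections (before/after) and one tissue injection, exactly as the
    clinical protocol pairs them.  Fully reproducible from ``seed``.
    """
    if n_subjects < 1:
        raise InvalidInputError("n_subjects must be >= 1")
    geom = geom or DeviceGeometry()
    fluid = fluid or FluidProps()
    spring_family = spring_family or default_spring_family(geom, fluid, p_ref)

    root = np.random.SeedSequence(seed)
    subjects: list[CohortSubject] = []
    for i, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        k = 10 ** rng.uniform(np.log10(k_range[0]), np.log10(k_range[1]))
        K = 10 ** rng.uniform(np.log10(K_range[0]), np.log10(K_range[1]))
        truth = TissueParams(k=k, K=K, p0=p_ref)
        dose = rng.uniform(*dose_range)
        dose = max(round(dose / volume_per_click), 2) * volume_per_click
        spring = spring_family(rng, dose)
        sid = f"S{i+1:02d}"
        inj_seeds = rng.integers(0, 2**31 - 1, size=3)
        common = dict(
            geom=geom, fluid=fluid, dose=dose, jitter_sd=jitter_sd,
            volume_per_click=volume_per_click, p_ref=p_ref, subject_id=sid,
        )
        air_pre = simulate_injection(spring, "air", seed=int(inj_seeds[0]), **common)
        tissue = simulate_injection(spring, truth, seed=int(inj_seeds[1]), **common)
        air_post = simulate_injection(spring, "air", seed=int(inj_seeds[2]), **common)
        subjects.append(CohortSubject(sid, truth, spring, air_pre, air_post, tissue))
    return subjects


def render_click_wav(
    train: ClickTrain,
    sample_rate: float = 44100.0,
    click_freq: float = 4000.0,
    decay_rate: float = 800.0,
    snr_db: float = 20.0,
    seed: int | None = None,
    pad: float = 0.1,
) -> tuple[np.ndarray, float]:
    """Render a click train as audio: damped sinusoids in Gaussian noise.

    Just enough acoustic realism to exercise the click detector; SNR is the
    ratio of click peak amplitude to noise SD in dB.  Returns
    ``(samples, sample_rate)``; write with :func:`write_wav`.
    """
    rng = np.random.default_rng(seed)
    dur = (train.times[-1] if train.n_clicks else 0.0) + pad + 0.05
    n = int(np.ceil(dur * sample_rate))
    noise_sd = 10 ** (-snr_db / 20.0)
    audio = rng.normal(0.0, noise_sd, size=n)
    tau = np.arange(0, int(0.01 * sample_rate)) / sample_rate
    pulse = np.exp(-decay_rate * tau) * np.sin(2 * np.pi * click_freq * tau)
    for t in train.times:
        i = int(round(t * sample_rate))
        seg = pulse[: n - i]
        audio[i : i + seg.size] += seg
    return audio, sample_rate


def write_wav(path, audio: np.ndarray, sample_rate: float) -> None:
    """Write float32 WAV via scipy."""
    from scipy.io import wavfile

    peak = np.max(np.abs(audio))
    if peak > 1.0:
        audio = audio / (1.01 * peak)
    wavfile.write(path, int(sample_rate), audio.astype(np.float32))
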