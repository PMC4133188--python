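"""Counter-pressure estimation from paired air/tissue injections and cohort summaries.

With the spring curve ``F(V)`` calibrated from air references, the absolute
pressure at the needle outlet during a tissue injection follows from the
device balance evaluated at the same delivered volume:

    p2(V) = F(V) / (π r_s²) − Δp_needle(Q_tissue(V)),

and the counter pressure is ``p2 − p_ref``.  Alignment is on the
delivered-volume coordinate, not on time, because the spring state depends
only on the piston position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from penpress.click_io import FlowSeries
from penpress.device_model import DeviceGeometry, FluidProps, SpringCurve, outlet_pressure
from penpress.errors import InsufficientDataError, InvalidInputError
from penpress.units import ATM, MBAR, UL


@dataclass(frozen=True)
class PressureSeries:
    """Needle-outlet (= tissue tip) pressure per click interval."""

    t_mid: np.ndarray
    V_mid: np.ndarray
    p2: np.ndarray          # absolute Pa
    p_ref: float = ATM
    subject_id: str = ""

    def __post_init__(self) -> None:
        for name in ("t_mid", "V_mid", "p2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.t_mid.shape == self.V_mid.shape == self.p2.shape):
            raise InvalidInputError("t_mid, V_mid, p2 must have equal shapes")
        if not np.all(np.isfinite(self.p2)):
            raise InvalidInputError("pressures must be finite")

    def __len__(self) -> int:
        return int(self.t_mid.size)

    @property
    def counter_pressure(self) -> np.ndarray:
        """Excess pressure over the reference, Pa."""
        return self.p2 - self.p_ref

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "t_mid_s": self.t_mid,
                "V_mid_uL": self.V_mid / UL,
                "p2_Pa": self.p2,
                "counter_pressure_mbar": self.counter_pressure / MBAR,
            }
        )


@dataclass(frozen=True)
class CohortStats:
    """Box-plot summary of per-subject mean counter pressures (Pa).

    The notch is the approximate 95% confidence interval for the median,
    ``median ± 1.57 · IQR / √n``.  Whiskers extend to the extreme included
    values.
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    notch_low: float
    notch_high: float
    n_included: int
    n_excluded: int
    included_values: np.ndarray

    def __post_init__(self) -> None:
        if self.n_included and not (self.q1 <= self.median <= self.q3):
            raise InvalidInputError("quartile ordering violated")


def tissue_pressure_series(
    spring: SpringCurve,
    tissue_flow: FlowSeries,
    geom: DeviceGeometry,
    fluid: FluidProps,
    p_ref: float = ATM,
) -> PressureSeries:
    """Needle-outlet pressure during a tissue injection.

    Evaluates the calibrated spring force at each interval's delivered-volume
    midpoint and subtracts the needle drop at the observed tissue flow rate.
    If the spring curve does not cover the tissue volume range a coverage
    warning is emitted and the curve is extrapolated flat.
    """
    if len(tissue_flow) == 0:
        raise InsufficientDataError("empty tissue flow series")
    if not spring.covers(tissue_flow.V_mid):
        warnings.warn(
            "spring calibration does not cover the tissue injection's volume range",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # extrapolation warned above, once
        F = spring(tissue_flow.V_mid)
    p2 = outlet_pressure(F, tissue_flow.Q, geom, fluid)
    return PressureSeries(
        t_mid=tissue_flow.t_mid,
        V_mid=tissue_flow.V_mid,
        p2=np.atleast_1d(p2),
        p_ref=p_ref,
        subject_id=tissue_flow.subject_id,
    )


def mean_counter_pressure(series: PressureSeries) -> float:
    """Unweighted mean counter pressure over the retained intervals (Pa).

    Every interval covers the same delivered volume, so the simple mean is
    also the volume-weighted mean.
    """
    if len(series) == 0:
        raise InsufficientDataError("empty pressure series")
    return float(np.mean(series.counter_pressure))


def cohort_boxstats(values, detection_floor: float = 10 * MBAR) -> CohortStats:
    """Box-plot statistics of per-subject mean counter pressures.

    Subjects whose mean counter pressure falls below ``detection_floor`` are
    excluded (no detectable flow change ⇒ tissue resistance below the
    method's sensitivity) and counted in ``n_excluded``.  Quartiles use
    linear interpolation of order statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("no values")
    included = values[values >= detection_floor]
    n = included.size
    n_exc = values.size - n
    if n == 0:
        nan = float("nan")
        return CohortStats(nan, nan, nan, nan, nan, nan, nan, 0, n_exc, included)
    q1, med, q3 = np.percentile(included, [25, 50, 75])
    iqr = q3 - q1
    half_notch = 1.57 * iqr / np.sqrt(n)
    return CohortStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(included.min()),
        whisker_high=float(included.max()),
        notch_low=float(med - half_notch),
        notch_high=float(med + half_notch),
        n_included=n,
        n_excluded=n_exc,
        included_values=included,
    )


def cohort_summary_frame(stats: CohortStats) -> pd.DataFrame:
    """One-row cohort summary in mbar for export."""
    return pd.DataFrame(
        [
            {
                "median_mbar": stats.median / MBAR,
                "q1_mbar": stats.q1 / MBAR,
                "q3_mbar": stats.q3 / MBAR,
                "whisker_low_mbar": stats.whisker_low / MBAR,
                "whisker_high_mbar": stats.whisker_high / MBAR,
                "notch_low_mbar": stats.notch_low / MBAR,
                "notch_high_mbar": stats.notch_high / MBAR,
                "n_included": stats.n_included,
                "n_excluded": stats.n_excluded,
            }
        ]
    )


def plot_cohort_box(stats: CohortStats, ax=None, label: str = "cohort"):
    """Notched box plot of the included per-subject means, in mbar."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 4))
    ax.boxplot(
        [stats.included_values / MBAR],
        notch=True,
        whis=(0, 100),
        tick_labels=[f"{label} (n={stats.n_included})"],
    )
    ax.set_ylabel("mean counter pressure [mbar]")
    return ax
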