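"""Click trains, click detection, and click → flow-rate conversion.

The pen emits one audible click per fixed delivered-volume increment
(nominally 10 µL).  A recording of the clicks therefore encodes the flow
rate: the volume increment divided by the inter-click interval is the mean
flow rate over that interval.  This module turns audio (or pre-extracted
click timestamp tables) into :class:`FlowSeries` objects that the rest of
the pipeline consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d

from penpress.errors import FormatError, InsufficientDataError, InvalidInputError
from penpress.units import UL, UL_PER_S, VOLUME_PER_CLICK

log = logging.getLogger(__name__)

_MEDIA = ("air", "tissue")


@dataclass(frozen=True)
class ClickTrain:
    """Ordered click timestamps with a fixed volume increment per click.

    Parameters
    ----------
    times
        Click times in seconds from the start of the recording, strictly
        increasing.
    volume_per_click
        Delivered volume per click in m³ (device constant, nominally 10 µL).
    subject_id
        Label of the subject / pen the train belongs to.
    medium
        ``"air"`` for reference injections at atmospheric pressure,
        ``"tissue"`` for subcutaneous injections.
    """

    times: np.ndarray
    volume_per_click: float = VOLUME_PER_CLICK
    subject_id: str = ""
    medium: str = "air"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise InvalidInputError("click times must be a 1-D sequence")
        if not np.all(np.isfinite(times)):
            raise InvalidInputError("click times must be finite")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise InvalidInputError("click times must be strictly increasing")
        if not self.volume_per_click > 0:
            raise InvalidInputError("volume_per_click must be positive")
        if self.medium not in _MEDIA:
            raise FormatError(
                f"medium must be one of {_MEDIA}, got {self.medium!r}"
            )

    @property
    def n_clicks(self) -> int:
        return int(self.times.size)

    @property
    def dose(self) -> float:
        """Volume implied by the train, ``n_clicks * volume_per_click`` (m³)."""
        return self.n_clicks * self.volume_per_click


@dataclass(frozen=True)
class FlowSeries:
    """Piecewise flow-rate estimates derived from a click train.

    ``Q[i] = volume_per_click / (t[i+1] - t[i])`` is the mean flow rate over
    interval ``i``, assigned to the interval midpoint ``t_mid[i]``.  ``V_mid``
    is the cumulative delivered volume at the interval midpoint: the device
    clicks once per completed volume increment, so the first click marks one
    increment delivered and ``V_mid[i] = (i + 3/2) * volume_per_click``.
    """

    t_mid: np.ndarray
    Q: np.ndarray
    V_mid: np.ndarray
    volume_per_click: float = VOLUME_PER_CLICK
    subject_id: str = ""
    medium: str = "air"
    truncated_tail: int = 0

    def __post_init__(self) -> None:
        for name in ("t_mid", "Q", "V_mid"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.t_mid.shape == self.Q.shape == self.V_mid.shape):
            raise InvalidInputError("t_mid, Q, V_mid must have equal shapes")
        if np.any(self.Q <= 0):
            raise InvalidInputError("flow rates must be strictly positive")

    def __len__(self) -> int:
        return int(self.t_mid.size)

    @property
    def total_volume(self) -> float:
        """Volume covered by the retained intervals (m³)."""
        return len(self) * self.volume_per_click

    def interpolator(self):
        """``Q(t)`` as a callable: linear between midpoints, constant beyond."""
        t, q = self.t_mid, self.Q

        def Q_of_t(x):
            return np.interp(x, t, q)

        return Q_of_t


def detect_clicks(
    audio: np.ndarray,
    sample_rate: float,
    threshold_sd: float = 6.0,
    refractory: float = 0.020,
    envelope_window: float = 0.001,
    volume_per_click: float = VOLUME_PER_CLICK,
    subject_id: str = "",
    medium: str = "air",
) -> ClickTrain:
    """Detect impulsive clicks in an audio stream.

    A moving-RMS envelope (window ``envelope_window``, default 1 ms) is
    thresholded at ``threshold_sd`` robust standard deviations above the
    envelope's noise floor; floor and SD are the median and scaled MAD of
    the envelope, which are insensitive to the clicks themselves because
    clicks are sparse (~10--20 Hz).  Each suprathreshold excursion
    contributes the location of its envelope peak, and peaks closer than
    ``refractory`` to the previous accepted click are discarded.

    Parameters
    ----------
    audio
        Sample sequence; multi-channel input is reduced to its first channel
        with a warning.
    sample_rate
        Sampling rate in Hz (must be positive).
    threshold_sd
        Detection threshold in units of the noise SD.
    refractory
        Minimum separation between reported clicks, in seconds.

    Returns
    -------
    ClickTrain
        Timestamps of accepted envelope peaks in seconds from stream start.
        Silent or too-short audio yields an empty train.
    """
    if not sample_rate > 0:
        raise InvalidInputError("sample_rate must be positive")
    audio = np.asarray(audio)
    if audio.ndim == 2:
        log.warning("multi-channel audio: using first channel only")
        audio = audio[:, 0]
    audio = audio.astype(float)
    if not np.all(np.isfinite(audio)):
        raise InvalidInputError("audio contains non-finite samples")

    win = max(int(round(envelope_window * sample_rate)), 1)
    if audio.size < 2 * win:
        return ClickTrain(np.empty(0), volume_per_click, subject_id, medium)

    envelope = np.sqrt(uniform_filter1d(audio**2, size=win, mode="nearest"))
    # noise floor and spread of the envelope itself, robust to the sparse clicks
    floor = np.median(envelope)
    spread = 1.4826 * np.median(np.abs(envelope - floor))
    if floor <= 0 and spread <= 0:  # silence
        return ClickTrain(np.empty(0), volume_per_click, subject_id, medium)

    above = envelope > floor + threshold_sd * spread
    if not above.any():
        return ClickTrain(np.empty(0), volume_per_click, subject_id, medium)

    # contiguous suprathreshold runs → peak index of each
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_stops = np.flatnonzero(d == -1)
    peaks = np.array(
        [s + np.argmax(envelope[s:e]) for s, e in zip(run_starts, run_stops)]
    )

    times = peaks / sample_rate
    accepted: list[float] = []
    for t in times:
        if not accepted or t - accepted[-1] >= refractory:
            accepted.append(t)
    return ClickTrain(np.array(accepted), volume_per_click, subject_id, medium)


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono WAV file (PCM 16/24/32-bit or float).

    Integer PCM is rescaled to [-1, 1].  Returns ``(samples, sample_rate)``.
    """
    rate, data = wavfile.read(path)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, float(rate)


def flow_from_clicks(
    train: ClickTrain,
    truncate_tail: int = 2,
    first_click_volume: float | None = None,
) -> FlowSeries:
    """Convert a click train to a flow-rate series.

    The last ``truncate_tail`` intervals are dropped: near the end of an
    injection the device deliberately reduces the spring force, producing a
    flow drop that does not reflect the spring curve, so the tail is excluded
    from analysis.

    ``first_click_volume`` is the delivered volume at the first click; it
    defaults to one ``volume_per_click`` (the click fires when an increment
    completes).  Air and tissue series use the same convention, so pairwise
    volume alignment never depends on it.

    Raises
    ------
    InsufficientDataError
        If fewer than ``2 + truncate_tail`` clicks are available.
    """
    if truncate_tail < 0:
        raise InvalidInputError("truncate_tail must be >= 0")
    n = train.n_clicks
    if n < 2 + truncate_tail:
        raise InsufficientDataError(
            f"need at least {2 + truncate_tail} clicks, got {n}"
        )
    t = train.times
    dt = np.diff(t)
    keep = dt.size - truncate_tail
    dt = dt[:keep]
    q = train.volume_per_click / dt
    t_mid = (t[:keep] + t[1 : keep + 1]) / 2
    v0 = train.volume_per_click if first_click_volume is None else first_click_volume
    v_mid = v0 + (np.arange(keep) + 0.5) * train.volume_per_click
    return FlowSeries(
        t_mid=t_mid,
        Q=q,
        V_mid=v_mid,
        volume_per_click=train.volume_per_click,
        subject_id=train.subject_id,
        medium=train.medium,
        truncated_tail=truncate_tail,
    )


def suggest_truncation(train: ClickTrain, drop_fraction: float = 0.30, window: int = 5) -> int:
    """Suggest how many trailing intervals look like the end-of-injection drop.

    Scans the last ``window`` inter-click intervals for a flow drop larger
    than ``drop_fraction`` between consecutive intervals and returns the
    number of trailing intervals from that point on.  Purely advisory: the
    caller decides whether to pass the value to :func:`flow_from_clicks`.
    Returns 0 if no drop is found.
    """
    if train.n_clicks < 3:
        return 0
    q = train.volume_per_click / np.diff(train.times)
    start = max(1, q.size - window)
    for i in range(start, q.size):
        if q[i] < (1.0 - drop_fraction) * q[i - 1]:
            return q.size - i
    return 0


# ---------------------------------------------------------------------------
# tabular I/O

_TABLE_COLUMNS = ["subject_id", "medium", "click_index", "time_s"]


def write_click_table(train: ClickTrain, path) -> None:
    """Write a click train as a CSV table (subject_id, medium, click_index, time_s)."""
    df = pd.DataFrame(
        {
            "subject_id": train.subject_id,
            "medium": train.medium,
            "click_index": np.arange(train.n_clicks),
            "time_s": train.times,
        }
    )
    df.to_csv(path, index=False)


def read_click_table(path, volume_per_click: float = VOLUME_PER_CLICK) -> ClickTrain:
    """Read a click-table CSV written by :func:`write_click_table`.

    Rows are sorted by time and re-indexed, so a shuffled ``click_index``
    column is accepted.  Unknown ``medium`` labels or missing columns raise
    :class:`FormatError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"click table missing columns: {missing}")
    media = set(df["medium"].unique())
    if not media <= set(_MEDIA):
        raise FormatError(f"unknown medium labels: {sorted(media - set(_MEDIA))}")
    if len(media) != 1 or df["subject_id"].nunique() != 1:
        raise FormatError("a click table must contain a single subject and medium")
    df = df.sort_values("time_s")
    return ClickTrain(
        times=df["time_s"].to_numpy(float),
        volume_per_click=volume_per_click,
        subject_id=str(df["subject_id"].iloc[0]),
        medium=str(df["medium"].iloc[0]),
    )


def write_flow_csv(flow: FlowSeries, path) -> None:
    """Export a flow series as CSV in human units (µL, µL/s)."""
    pd.DataFrame(
        {
            "subject_id": flow.subject_id,
            "medium": flow.medium,
            "t_mid_s": flow.t_mid,
            "Q_uL_per_s": flow.Q / UL_PER_S,
            "V_mid_uL": flow.V_mid / UL,
        }
    ).to_csv(path, index=False)
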