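"""Cleaning, angle conversion, despiking, segmentation, and velocity.

The horizontal gaze angle is ``atan(gd_x / gd_z)`` converted to degrees,
negative when the eyes move right and positive when they move left.
Only samples whose validity bitmask equals 31 (all fields valid) enter
the analysis.  Spike noise is removed with an order-10 running median
over the whole per-eye stream before trials are segmented, and velocity
is computed with time-aware finite differences on the actual host
timestamps because the recorded sampling intervals are irregular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eyedata_io import ALL_VALID, TrialEvent

__all__ = [
    "TrialWindow",
    "UnanalyzableTrialError",
    "gaze_angle_deg",
    "clean",
    "despike",
    "segment_trial",
    "velocity",
    "TASK_WINDOWS_MS",
]

#: per-task search window relative to stimulus onset, closed bounds (ms)
TASK_WINDOWS_MS = {"pro": (100.0, 500.0), "anti": (125.0, 750.0)}

SIGNAL_KINDS = ("gaze_deg", "pupil_pos_x")


class UnanalyzableTrialError(ValueError):
    """A trial whose signal segment cannot support detection."""


@dataclass
class TrialWindow:
    """A cleaned, filtered per-trial signal segment, times relative to onset.

    ``velocity`` is defined at the midpoints between consecutive samples
    (``velocity_times_ms``), so it has one element fewer than ``values``.
    """

    trial_index: int
    eye: str
    signal_kind: str  # "gaze_deg" | "pupil_pos_x"
    times_ms: np.ndarray
    values: np.ndarray
    velocity: np.ndarray | None = None
    velocity_times_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")
        if self.times_ms.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")
        if np.any(np.diff(self.times_ms) < 0):
            # ties are tolerated on construction; velocity() drops them
            raise ValueError("window times must be non-decreasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window values must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.times_ms.size)


def gaze_angle_deg(gd_x, gd_z):
    """Horizontal gaze angle in degrees from normalized direction components.

    ``atan(gd_x / gd_z)`` in radians, converted to degrees.  Scalar or
    array inputs; ``gd_z == 0`` raises for scalars and yields NaN (with a
    warning) for arrays, since the direction is undefined there.
    """
    gd_x = np.asarray(gd_x, dtype=float)
    gd_z = np.asarray(gd_z, dtype=float)
    scalar = gd_x.ndim == 0 and gd_z.ndim == 0
    zero = gd_z == 0
    if scalar:
        if zero:
            raise ValueError("gaze direction undefined: gd_z is zero")
        return float(np.degrees(np.arctan(gd_x / gd_z)))
    if np.any(zero):
        warnings.warn(
            f"{int(np.count_nonzero(zero))} sample(s) with gd_z == 0 set to NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.degrees(np.arctan(np.divide(gd_x, gd_z)))
    out = np.where(zero, np.nan, out)
    return out


def clean(frame: pd.DataFrame, eye: str) -> tuple[pd.DataFrame, float]:
    """Keep only rows whose validity for ``eye`` equals 31.

    Returns the retained rows (values untouched) and the retention ratio.
    Raises if nothing survives.
    """
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
    validity = frame[f"{eye}_validity"].to_numpy()
    mask = validity == ALL_VALID
    if not mask.any():
        raise ValueError(f"no valid samples for {eye} eye (validity == 31)")
    retained = frame.loc[mask]
    return retained, float(mask.mean())


def despike(series, order: int = 10) -> np.ndarray:
    """Running median of the stated order; length-preserving.

    Windows are centered (``[i - (order-1)//2, i + order//2]``) and clip
    to the available samples at the boundaries.  Even-length windows take
    the lower of the two central order statistics: averaging them would
    act as an extra two-sample smoother and visibly blunt the velocity
    peaks that the detector measures, whereas the lower median leaves
    monotone stretches untouched.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("despike expects a 1-D series")
    n = x.size
    if n <= order:
        raise ValueError(f"series length {n} must exceed filter order {order}")
    lo = (order - 1) // 2
    hi = order // 2
    out = np.empty(n)
    # interior: full windows, vectorized; lower median = order statistic lo
    windows = np.lib.stride_tricks.sliding_window_view(x, order)
    out[lo : n - hi] = np.partition(windows, lo, axis=1)[:, lo]
    # boundaries: clipped windows
    for i in range(lo):
        w = x[: i + hi + 1]
        out[i] = np.partition(w, (w.size - 1) // 2)[(w.size - 1) // 2]
    for i in range(n - hi, n):
        w = x[i - lo :]
        out[i] = np.partition(w, (w.size - 1) // 2)[(w.size - 1) // 2]
    return out


def segment_trial(
    times_ms: np.ndarray,
    values: np.ndarray,
    event: TrialEvent,
    signal_kind: str,
    eye: str,
    min_samples: int = 10,
    window_ms: tuple[float, float] | None = None,
) -> TrialWindow:
    """Extract the task-specific search window around one stimulus onset.

    The window is ``[onset+100, onset+500]`` ms for pro-saccade trials
    and ``[onset+125, onset+750]`` ms for anti-saccade trials, both
    bounds inclusive; returned times are relative to the onset.  A
    window holding fewer than ``min_samples`` samples raises
    :class:`UnanalyzableTrialError`.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    values = np.asarray(values, dtype=float)
    lo_off, hi_off = window_ms if window_ms is not None else TASK_WINDOWS_MS[event.task]
    lo = event.onset_host_time_ms + lo_off
    hi = event.onset_host_time_ms + hi_off
    start = int(np.searchsorted(times_ms, lo, side="left"))
    stop = int(np.searchsorted(times_ms, hi, side="right"))
    t = times_ms[start:stop]
    v = values[start:stop]
    finite = np.isfinite(v)
    t, v = t[finite], v[finite]
    if t.size < min_samples:
        raise UnanalyzableTrialError(
            f"trial {event.trial_index}: only {t.size} samples in "
            f"[{lo_off}, {hi_off}] ms window (minimum {min_samples})"
        )
    return TrialWindow(
        trial_index=event.trial_index,
        eye=eye,
        signal_kind=signal_kind,
        times_ms=t - event.onset_host_time_ms,
        values=v,
    )


def velocity(window: TrialWindow) -> TrialWindow:
    """Fill per-sample velocity via finite differences on actual timestamps.

    Differences between consecutive samples are assigned to the interval
    midpoints, which keeps the estimate phase-neutral and exact for
    affine signals regardless of timing jitter.  Units: signal units per
    second (deg/s for gaze, 1/s for pupil position).  Samples repeating
    the previous timestamp are dropped before differencing.
    """
    t = window.times_ms
    x = window.values
    keep = np.concatenate(([True], np.diff(t) > 0))
    if not keep.all():
        t, x = t[keep], x[keep]
        window.times_ms, window.values = t, x
    if t.size < 3:
        raise UnanalyzableTrialError(
            f"trial {window.trial_index}: fewer than 3 distinct-timestamp samples"
        )
    dt_s = np.diff(t) / 1000.0
    window.velocity = np.diff(x) / dt_s
    window.velocity_times_ms = 0.5 * (t[:-1] + t[1:])
    return window
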