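"""Shared helpers for the test suite: constructed windows and brute-force oracles.

The oracles here are deliberately independent of the package internals:
plain-Python medians over explicit window bounds, and a literal
re-implementation of the five-case decision rules scanning all local
extrema, so they can arbitrate the vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np

from saccadekit.preprocess import TrialWindow, velocity

FRAME_MS = 1000.0 / 120.0

# ---------------------------------------------------------------------------
# constructed trial windows


def rc01(t, duration):
    """Raised-cosine unit step (reference copy for constructing traces)."""
    t = np.asarray(t, dtype=float)
    if duration <= 0:
        return (t >= 0).astype(float)
    u = np.clip(t / duration, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def make_window(
    segments,
    task="pro",
    trial_index=0,
    eye="left",
    signal_kind="gaze_deg",
    window=None,
    phase=0.0,
    with_velocity=True,
):
    """Build a TrialWindow from raised-cosine movement segments.

    ``segments`` is a list of (onset_ms, delta, duration_ms): the trace
    moves by ``delta`` starting at ``onset_ms`` (relative to stimulus
    onset) over ``duration_ms``.
    """
    lo, hi = window if window is not None else ((100.0, 500.0) if task == "pro" else (125.0, 750.0))
    t = np.arange(lo + phase, hi + 1e-9, FRAME_MS)
    values = np.zeros_like(t)
    for onset, delta, duration in segments:
        values = values + delta * rc01(t - onset, duration)
    win = TrialWindow(
        trial_index=trial_index, eye=eye, signal_kind=signal_kind, times_ms=t, values=values
    )
    if with_velocity:
        velocity(win)
    return win


# ---------------------------------------------------------------------------
# brute-force despike oracle


def brute_force_median_filter(x, order=10):
    """Per-window lower median over the same clipped window bounds."""
    x = list(map(float, x))
    n = len(x)
    lo = (order - 1) // 2
    hi = order // 2
    out = []
    for i in range(n):
        window = sorted(x[max(0, i - lo) : min(n, i + hi + 1)])
        out.append(window[(len(window) - 1) // 2])
    return out


# ---------------------------------------------------------------------------
# brute-force five-case classification oracle


def brute_force_classify(values, vel, want_sign, no_move, peak_thr=0.5, onset_thr=0.25):
    """Literal evaluation of the five-case rules over all local extrema.

    Returns a dict with case_id, is_error, onset index (into the
    velocity series) or None, and the selected peak index or None.
    """
    values = list(map(float, values))
    vel = list(map(float, vel))
    if max(values) - min(values) < no_move:
        return {"case_id": 5, "is_error": True, "onset": None, "selected": None}
    vmax = max(abs(v) for v in vel)
    if vmax == 0:
        return {"case_id": 5, "is_error": True, "onset": None, "selected": None}
    vn = [v / vmax for v in vel]

    extrema = []
    for i in range(1, len(vn) - 1):
        if vn[i - 1] < vn[i] > vn[i + 1] or vn[i - 1] > vn[i] < vn[i + 1]:
            extrema.append(i)
    top = max(range(len(vn)), key=lambda i: abs(vn[i]))
    if top not in extrema:
        extrema.append(top)
    extrema.sort()
    peaks = [i for i in extrema if abs(vn[i]) > peak_thr]
    if not peaks:
        return {"case_id": 5, "is_error": True, "onset": None, "selected": None}

    def sign(v):
        return int(math.copysign(1, v)) if v else 0

    first = peaks[0]
    is_error = False
    case = None
    if sign(vel[first]) == want_sign:
        selected = first
    else:
        matching = [p for p in peaks if sign(vel[p]) == want_sign]
        if matching:
            selected = matching[0]
            case = 3
        else:
            selected = first
            is_error = True

    later = [p for p in peaks if p > selected]
    has_return = any(sign(vel[p]) == -sign(vel[selected]) for p in later)
    if case == 3:
        case = 4 if has_return else 3
    else:
        case = 2 if has_return else 1

    onset = selected
    while onset > 0 and abs(vn[onset - 1]) >= onset_thr:
        onset -= 1
    return {"case_id": case, "is_error": is_error, "onset": onset, "selected": selected}
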