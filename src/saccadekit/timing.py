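"""Sampling-interval diagnostics for the two recording clocks.

Inter-sample intervals are computed separately from the host clock and
the device timestamp.  The host series is smoothed with an order-10
running median and the device series with a centered 5-sample moving
average; the stabilization point is the first index where the smoothed
interval falls and stays below 8 ms for a sustained run, marking the
end of the recording warm-up regime.  Device-clock intervals are also
binned into the characteristic {8, 9, 16, 17} ms classes (the +-1 ms
split reflects integer clock granularity; 16/17 ms indicates a skipped
frame), and consecutive rows sharing both device timestamp and frame
sequence are flagged as duplicate reads — with differing payload they
carry the known timestamp-bug signature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import despike

__all__ = [
    "TimingReport",
    "intervals",
    "smooth",
    "stabilization_index",
    "find_duplicates",
    "classify_intervals",
    "timing_report",
]

INTERVAL_CLASSES = (8, 9, 16, 17)
STABILIZATION_THRESHOLD_MS = 8.0
STABILIZATION_RUN_LENGTH = 50

#: columns that constitute the per-row payload (everything but the clocks)
_PAYLOAD_EXCLUDED = ("host_time_ms",)
_KEY_COLUMNS = ("device_timestamp_ms", "frame_sequence")


def intervals(times_ms) -> np.ndarray:
    """First differences of a timestamp series, in milliseconds.

    Negative deltas (non-monotone input) are preserved — a diagnostic
    must not hide clock faults — but trigger a warning.
    """
    t = np.asarray(times_ms, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples to compute intervals")
    deltas = np.diff(t)
    n_neg = int(np.count_nonzero(deltas < 0))
    if n_neg:
        warnings.warn(f"{n_neg} negative sampling interval(s) found", stacklevel=2)
    return deltas


def smooth(deltas, clock: str) -> np.ndarray:
    """Clock-specific smoothing of an interval series.

    ``clock="host"``: running median, order 10. ``clock="device"``:
    centered moving average, window 5 (shrinking at the boundaries).
    """
    x = np.asarray(deltas, dtype=float)
    if clock == "host":
        return despike(x, order=10)
    if clock == "device":
        if x.size <= 5:
            raise ValueError(f"series length {x.size} must exceed window 5")
        return (
            pd.Series(x).rolling(window=5, center=True, min_periods=1).mean().to_numpy()
        )
    raise ValueError(f"clock must be 'host' or 'device', got {clock!r}")


def stabilization_index(
    filtered_deltas,
    threshold_ms: float = STABILIZATION_THRESHOLD_MS,
    run_length: int = STABILIZATION_RUN_LENGTH,
) -> int | None:
    """First index opening a sustained run of sub-threshold intervals.

    Returns the first ``i`` such that every filtered interval in
    ``[i, i + run_length)`` is strictly below ``threshold_ms``; a single
    crossing in noise does not count.  ``None`` if no such run exists.
    """
    x = np.asarray(filtered_deltas, dtype=float)
    below = x < threshold_ms
    if below.size < run_length:
        return None
    run = np.convolve(below.astype(int), np.ones(run_length, dtype=int), mode="valid")
    hits = np.flatnonzero(run == run_length)
    return int(hits[0]) if hits.size else None


def find_duplicates(samples: pd.DataFrame) -> list[dict]:
    """Flag consecutive rows that repeat the device timestamp and frame number.

    Each flagged pair is reported at the index of its first row with a
    kind: ``"timestamp_bug"`` when any payload field differs between the
    two rows (the device clock failed to advance) or ``"double_read"``
    when the rows are identical in every field except the host clock.
    """
    if len(samples) < 2:
        return []
    keys = [samples[c].to_numpy() for c in _KEY_COLUMNS]
    same_key = np.logical_and.reduce([k[1:] == k[:-1] for k in keys])
    payload_cols = [
        c for c in samples.columns if c not in _PAYLOAD_EXCLUDED and c not in _KEY_COLUMNS
    ]
    same_payload = np.ones(len(samples) - 1, dtype=bool)
    for c in payload_cols:
        v = samples[c].to_numpy()
        a, b = v[:-1], v[1:]
        if np.issubdtype(v.dtype, np.floating):
            eq = (a == b) | (np.isnan(a) & np.isnan(b))
        else:
            eq = a == b
        same_payload &= eq
    out = []
    for i in np.flatnonzero(same_key):
        out.append(
            {"index": int(i), "kind": "double_read" if same_payload[i] else "timestamp_bug"}
        )
    return out


def classify_intervals(deltas) -> dict[str, int]:
    """Count device-clock intervals in the {8, 9, 16, 17, other} ms classes.

    Deltas are rounded to the nearest integer millisecond first (the
    device clock has integer granularity).
    """
    rounded = np.rint(np.asarray(deltas, dtype=float)).astype(int)
    counts = {str(c): int(np.count_nonzero(rounded == c)) for c in INTERVAL_CLASSES}
    counts["other"] = int(rounded.size - sum(counts.values()))
    return counts


@dataclass
class TimingReport:
    """Per-clock interval series and the derived diagnostics."""

    raw_intervals_ms: dict[str, np.ndarray]
    filtered_intervals_ms: dict[str, np.ndarray]
    stabilization_index_: dict[str, int | None]
    stabilization_time_s: dict[str, float | None]
    duplicates: list[dict]
    interval_class_counts: dict[str, int]
    n_samples: int
    n_negative_intervals: dict[str, int]

    @property
    def duplicate_indices(self) -> list[int]:
        return [d["index"] for d in self.duplicates]

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "stabilization_index": self.stabilization_index_,
            "stabilization_time_s": self.stabilization_time_s,
            "duplicates": self.duplicates,
            "interval_class_counts": self.interval_class_counts,
            "n_negative_intervals": self.n_negative_intervals,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def intervals_frame(self) -> pd.DataFrame:
        """Raw and filtered interval series for plotting or export."""
        return pd.DataFrame(
            {
                "host_raw_ms": self.raw_intervals_ms["host"],
                "host_filtered_ms": self.filtered_intervals_ms["host"],
                "device_raw_ms": self.raw_intervals_ms["device"],
                "device_filtered_ms": self.filtered_intervals_ms["device"],
            }
        )


def timing_report(
    samples: pd.DataFrame,
    threshold_ms: float = STABILIZATION_THRESHOLD_MS,
    run_length: int = STABILIZATION_RUN_LENGTH,
) -> TimingReport:
    """Build the full sampling diagnostics for one sample log."""
    raw: dict[str, np.ndarray] = {}
    filtered: dict[str, np.ndarray] = {}
    stab_idx: dict[str, int | None] = {}
    stab_time: dict[str, float | None] = {}
    n_neg: dict[str, int] = {}
    clock_cols = {"host": "host_time_ms", "device": "device_timestamp_ms"}
    for clock, col in clock_cols.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            deltas = intervals(samples[col].to_numpy(dtype=float))
        raw[clock] = deltas
        n_neg[clock] = int(np.count_nonzero(deltas < 0))
        filtered[clock] = smooth(deltas, clock)
        idx = stabilization_index(filtered[clock], threshold_ms, run_length)
        stab_idx[clock] = idx
        stab_time[clock] = float(deltas[:idx].sum() / 1000.0) if idx is not None else None
    return TimingReport(
        raw_intervals_ms=raw,
        filtered_intervals_ms=filtered,
        stabilization_index_=stab_idx,
        stabilization_time_s=stab_time,
        duplicates=find_duplicates(samples),
        interval_class_counts=classify_intervals(raw["device"]),
        n_samples=len(samples),
        n_negative_intervals=n_neg,
    )
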