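"""Data model and TSV readers/writers for eye-sample and trial-event logs.

A sample log holds one row per tracker frame: frame sequence, the
device's millisecond timestamp, the host clock in milliseconds, and per
eye a validity bitmask, eye openness, pupil diameter, normalized pupil
position, gaze origin, and normalized gaze direction.  Per-eye fields
whose validity bit is unset are serialized as ``NA``.

The host clock is trusted for all trial alignment; the device timestamp
is retained but known to be unreliable on some tracker firmware (it can
stall or read zero), so nothing downstream depends on it except the
sampling diagnostics that examine it deliberately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EyeState",
    "EyeSample",
    "ValidityFlags",
    "TrialEvent",
    "SAMPLE_COLUMNS",
    "EVENT_COLUMNS",
    "decode_validity",
    "encode_validity",
    "read_samples",
    "read_samples_frame",
    "write_samples",
    "read_events",
    "write_events",
    "samples_to_frame",
    "frame_to_samples",
]

EYES = ("left", "right")

#: validity bit values, in bitmask order
VALIDITY_BITS = {
    "gaze_origin": 1,
    "gaze_direction": 2,
    "pupil_diameter": 4,
    "eye_openness": 8,
    "pupil_position": 16,
}
ALL_VALID = 31

#: per-eye column suffixes and the validity bit that guards each
_EYE_FIELDS = (
    ("validity", None),
    ("openness", "eye_openness"),
    ("pupil_diameter_mm", "pupil_diameter"),
    ("pupil_pos_x", "pupil_position"),
    ("pupil_pos_y", "pupil_position"),
    ("gaze_origin_x_mm", "gaze_origin"),
    ("gaze_origin_y_mm", "gaze_origin"),
    ("gaze_origin_z_mm", "gaze_origin"),
    ("gaze_dir_x", "gaze_direction"),
    ("gaze_dir_y", "gaze_direction"),
    ("gaze_dir_z", "gaze_direction"),
)

SAMPLE_COLUMNS = tuple(
    ["frame_sequence", "device_timestamp_ms", "host_time_ms"]
    + [f"{eye}_{name}" for eye in EYES for name, _ in _EYE_FIELDS]
)

EVENT_COLUMNS = ("trial_index", "task", "side", "onset_host_time_ms", "offset_host_time_ms")

#: 100 ns host ticks per millisecond (for logs recorded with a tick clock)
TICKS_PER_MS = 10_000


class SampleLogError(ValueError):
    """Malformed sample or event log."""


@dataclass(frozen=True)
class ValidityFlags:
    """Decoded per-field validity of one eye's sample."""

    gaze_origin: bool = False
    gaze_direction: bool = False
    pupil_diameter: bool = False
    eye_openness: bool = False
    pupil_position: bool = False

    @property
    def all_valid(self) -> bool:
        return self.encode() == ALL_VALID

    def encode(self) -> int:
        return encode_validity(self)


def decode_validity(value: int) -> ValidityFlags:
    """Decode an integer validity bitmask (0-31) into per-field flags."""
    value = int(value)
    if not (0 <= value <= ALL_VALID):
        raise ValueError(f"validity bitmask must lie in [0, {ALL_VALID}], got {value}")
    return ValidityFlags(**{name: bool(value & bit) for name, bit in VALIDITY_BITS.items()})


def encode_validity(flags: ValidityFlags) -> int:
    """Encode per-field flags back into the integer bitmask."""
    return sum(bit for name, bit in VALIDITY_BITS.items() if getattr(flags, name))


@dataclass(frozen=True)
class EyeState:
    """One eye's fields for a single frame; invalid fields are NaN."""

    validity: int
    openness: float
    pupil_diameter_mm: float
    pupil_pos: tuple[float, float]
    gaze_origin_mm: tuple[float, float, float]
    gaze_dir: tuple[float, float, float]

    @property
    def flags(self) -> ValidityFlags:
        return decode_validity(self.validity)


@dataclass(frozen=True)
class EyeSample:
    """One binocular tracker frame."""

    frame_sequence: int
    device_timestamp_ms: int
    host_time_ms: float
    left: EyeState
    right: EyeState

    def eye(self, which: str) -> EyeState:
        if which not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {which!r}")
        return getattr(self, which)


@dataclass(frozen=True)
class TrialEvent:
    """Stimulus onset/offset of one scored trial, on the host clock."""

    trial_index: int
    task: str
    side: str
    onset_host_time_ms: float
    offset_host_time_ms: float

    def __post_init__(self) -> None:
        if self.task not in ("pro", "anti"):
            raise ValueError(f"task must be 'pro' or 'anti', got {self.task!r}")
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")
        if self.offset_host_time_ms <= self.onset_host_time_ms:
            raise ValueError("event offset must come after onset")


def _format_cell(value) -> str:
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return "NA"
        return repr(float(value))
    return str(value)


def _mask_invalid_fields(frame: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with per-eye fields NaN wherever their bit is unset."""
    out = frame.copy()
    for eye in EYES:
        validity = out[f"{eye}_validity"].to_numpy(dtype=np.int64)
        for name, guard in _EYE_FIELDS:
            if guard is None:
                continue
            bit = VALIDITY_BITS[guard]
            col = f"{eye}_{name}"
            masked = out[col].to_numpy(dtype=float).copy()
            masked[(validity & bit) == 0] = np.nan
            out[col] = masked
    return out


def write_samples(samples, path: str | Path) -> None:
    """Write samples (DataFrame or iterable of EyeSample) as TSV.

    Fields whose validity bit is unset are written as ``NA``; all other
    floats are written at full precision so a read round-trips exactly.
    """
    frame = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    missing = [c for c in SAMPLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SampleLogError(f"sample frame is missing columns: {missing}")
    frame = _mask_invalid_fields(frame)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# host_time_unit: ms\n")
        fh.write("\t".join(SAMPLE_COLUMNS) + "\n")
        ints = {"frame_sequence", "device_timestamp_ms"} | {f"{e}_validity" for e in EYES}
        cols = [frame[c].to_numpy() for c in SAMPLE_COLUMNS]
        for row in zip(*cols):
            fh.write(
                "\t".join(
                    str(int(v)) if name in ints else _format_cell(v)
                    for name, v in zip(SAMPLE_COLUMNS, row)
                )
                + "\n"
            )


def read_samples_frame(path: str | Path, host_time_unit: str | None = None) -> pd.DataFrame:
    """Read a sample log into a DataFrame keyed by ``SAMPLE_COLUMNS``.

    ``host_time_unit`` may be ``"ms"`` (default) or ``"ticks"`` (100 ns
    host ticks, converted to milliseconds on read); a ``# host_time_unit``
    comment in the file header takes effect when the argument is None.
    """
    path = Path(path)
    header_unit = "ms"
    skip = 0
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            if "host_time_unit:" in first:
                header_unit = first.split("host_time_unit:")[1].strip()
            skip += 1
            first = fh.readline()
    unit = host_time_unit or header_unit
    if unit not in ("ms", "ticks"):
        raise SampleLogError(f"unknown host_time_unit {unit!r}")

    frame = pd.read_csv(
        path, sep="\t", skiprows=skip, na_values=["NA"], float_precision="round_trip"
    )
    missing = [c for c in SAMPLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SampleLogError(f"{path}: missing columns: {missing}")

    for eye in EYES:
        col = f"{eye}_validity"
        validity = frame[col]
        if validity.isna().any():
            lineno = int(validity.index[validity.isna()][0]) + skip + 2
            raise SampleLogError(f"{path}:{lineno}: missing validity value")
        bad = (validity < 0) | (validity > ALL_VALID)
        if bad.any():
            lineno = int(validity.index[bad][0]) + skip + 2
            raise SampleLogError(
                f"{path}:{lineno}: validity {int(validity[bad].iloc[0])} out of range [0, 31]"
            )
        frame[col] = validity.astype(np.int64)

    if unit == "ticks":
        frame["host_time_ms"] = frame["host_time_ms"] / TICKS_PER_MS

    host = frame["host_time_ms"].to_numpy()
    if np.any(np.diff(host) < 0):
        warnings.warn(
            f"{path}: host_time_ms is not monotone non-decreasing; rows kept as-is",
            stacklevel=2,
        )
    return frame[list(SAMPLE_COLUMNS)]


def read_samples(path: str | Path, host_time_unit: str | None = None) -> list[EyeSample]:
    """Read a sample log as an ordered list of :class:`EyeSample`."""
    return frame_to_samples(read_samples_frame(path, host_time_unit=host_time_unit))


def samples_to_frame(samples: Iterable[EyeSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = {
            "frame_sequence": s.frame_sequence,
            "device_timestamp_ms": s.device_timestamp_ms,
            "host_time_ms": s.host_time_ms,
        }
        for eye in EYES:
            st = s.eye(eye)
            row[f"{eye}_validity"] = st.validity
            row[f"{eye}_openness"] = st.openness
            row[f"{eye}_pupil_diameter_mm"] = st.pupil_diameter_mm
            row[f"{eye}_pupil_pos_x"], row[f"{eye}_pupil_pos_y"] = st.pupil_pos
            (
                row[f"{eye}_gaze_origin_x_mm"],
                row[f"{eye}_gaze_origin_y_mm"],
                row[f"{eye}_gaze_origin_z_mm"],
            ) = st.gaze_origin_mm
            (
                row[f"{eye}_gaze_dir_x"],
                row[f"{eye}_gaze_dir_y"],
                row[f"{eye}_gaze_dir_z"],
            ) = st.gaze_dir
        rows.append(row)
    return pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))


def frame_to_samples(frame: pd.DataFrame) -> list[EyeSample]:
    out: list[EyeSample] = []
    cols = {c: frame[c].to_numpy() for c in SAMPLE_COLUMNS}
    for i in range(len(frame)):
        states = {}
        for eye in EYES:
            states[eye] = EyeState(
                validity=int(cols[f"{eye}_validity"][i]),
                openness=float(cols[f"{eye}_openness"][i]),
                pupil_diameter_mm=float(cols[f"{eye}_pupil_diameter_mm"][i]),
                pupil_pos=(
                    float(cols[f"{eye}_pupil_pos_x"][i]),
                    float(cols[f"{eye}_pupil_pos_y"][i]),
                ),
                gaze_origin_mm=(
                    float(cols[f"{eye}_gaze_origin_x_mm"][i]),
                    float(cols[f"{eye}_gaze_origin_y_mm"][i]),
                    float(cols[f"{eye}_gaze_origin_z_mm"][i]),
                ),
                gaze_dir=(
                    float(cols[f"{eye}_gaze_dir_x"][i]),
                    float(cols[f"{eye}_gaze_dir_y"][i]),
                    float(cols[f"{eye}_gaze_dir_z"][i]),
                ),
            )
        out.append(
            EyeSample(
                frame_sequence=int(cols["frame_sequence"][i]),
                device_timestamp_ms=int(cols["device_timestamp_ms"][i]),
                host_time_ms=float(cols["host_time_ms"][i]),
                left=states["left"],
                right=states["right"],
            )
        )
    return out


def write_events(events: Sequence[TrialEvent], path: str | Path) -> None:
    """Write trial events as TSV, sorted by onset."""
    events = sorted(events, key=lambda e: e.onset_host_time_ms)
    _check_disjoint(events)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for e in events:
            fh.write(
                f"{e.trial_index}\t{e.task}\t{e.side}\t"
                f"{e.onset_host_time_ms!r}\t{e.offset_host_time_ms!r}\n"
            )


def read_events(path: str | Path) -> list[TrialEvent]:
    """Read a trial-event log; events are returned sorted by onset."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != list(EVENT_COLUMNS):
        raise SampleLogError(f"{path}: missing or malformed event header")
    events = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(EVENT_COLUMNS):
            raise SampleLogError(f"{path}:{lineno}: expected {len(EVENT_COLUMNS)} columns")
        try:
            events.append(
                TrialEvent(
                    trial_index=int(parts[0]),
                    task=parts[1],
                    side=parts[2],
                    onset_host_time_ms=float(parts[3]),
                    offset_host_time_ms=float(parts[4]),
                )
            )
        except ValueError as exc:
            raise SampleLogError(f"{path}:{lineno}: {exc}") from exc
    events.sort(key=lambda e: e.onset_host_time_ms)
    _check_disjoint(events)
    return events


def _check_disjoint(events: Sequence[TrialEvent]) -> None:
    for prev, cur in zip(events, events[1:]):
        if cur.onset_host_time_ms < prev.offset_host_time_ms:
            raise SampleLogError(
                f"overlapping stimulus windows: trial {cur.trial_index} onset "
                f"{cur.onset_host_time_ms} precedes trial {prev.trial_index} offset "
                f"{prev.offset_host_time_ms}"
            )
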