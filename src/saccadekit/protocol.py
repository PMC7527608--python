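"""Standardized pro-/anti-saccade session protocol and stimulus geometry.

The session schedule follows the standardized flow: 10 pro-saccade
practice trials, 60 pro trials, a break, 4 anti practice trials, three
blocks of 40 anti trials separated by breaks, and a final block of 60
pro trials — 120 scored trials per task.  Within every phase the two
stimulus sides appear equally often in a seeded random order, and the
fore-periods (duration of the central fixation target) are drawn from
[1.0, 3.5] s and adjusted so that each phase's mean is exactly 1.5 s.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

__all__ = [
    "GeometryConfig",
    "TrialSpec",
    "Phase",
    "SessionProtocol",
    "generate_session_protocol",
    "target_world_geometry",
    "write_protocol",
    "read_protocol",
]

FORE_PERIOD_MIN_S = 1.0
FORE_PERIOD_MAX_S = 3.5
FORE_PERIOD_MEAN_S = 1.5

#: (name, task, n_trials, is_practice, break_after)
DEFAULT_PHASE_PLAN = (
    ("pro_practice", "pro", 10, True, False),
    ("pro_1", "pro", 60, False, True),
    ("anti_practice", "anti", 4, True, False),
    ("anti_1", "anti", 40, False, True),
    ("anti_2", "anti", 40, False, True),
    ("anti_3", "anti", 40, False, False),
    ("pro_2", "pro", 60, False, False),
)


class GeometryError(ValueError):
    """Raised when the stimulus geometry violates its constraints."""


@dataclass(frozen=True)
class GeometryConfig:
    """Stimulus geometry: viewing distance and target angles.

    Defaults: lateral targets at 8 degrees eccentricity, 1 degree
    diameter, viewed from 7 m.  Eccentricities outside the recommended
    8-10 degree band are rejected unless ``allow_nonstandard`` is set.
    """

    viewing_distance_m: float = 7.0
    target_eccentricity_deg: float = 8.0
    target_diameter_deg: float = 1.0
    central_target_diameter_deg: float = 1.0
    allow_nonstandard: bool = False

    RECOMMENDED_ECCENTRICITY_BAND = (8.0, 10.0)

    def validate(self) -> None:
        for name in (
            "viewing_distance_m",
            "target_eccentricity_deg",
            "target_diameter_deg",
            "central_target_diameter_deg",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise GeometryError(f"{name} must be strictly positive, got {value!r}")
        lo, hi = self.RECOMMENDED_ECCENTRICITY_BAND
        if not self.allow_nonstandard and not (lo <= self.target_eccentricity_deg <= hi):
            raise GeometryError(
                f"target_eccentricity_deg={self.target_eccentricity_deg} is outside the "
                f"recommended [{lo}, {hi}] degree band; set allow_nonstandard=True to override"
            )


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled saccade trial."""

    trial_index: int
    phase: str
    task: str  # "pro" | "anti"
    side: str  # "right" | "left"
    fore_period_s: float
    is_practice: bool

    def __post_init__(self) -> None:
        if self.task not in ("pro", "anti"):
            raise ValueError(f"task must be 'pro' or 'anti', got {self.task!r}")
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")
        if not (FORE_PERIOD_MIN_S <= self.fore_period_s <= FORE_PERIOD_MAX_S):
            raise ValueError(
                f"fore_period_s must lie in [{FORE_PERIOD_MIN_S}, {FORE_PERIOD_MAX_S}], "
                f"got {self.fore_period_s}"
            )


@dataclass(frozen=True)
class Phase:
    name: str
    task: str
    is_practice: bool
    break_after: bool
    trials: tuple[TrialSpec, ...]


@dataclass(frozen=True)
class SessionProtocol:
    """The full ordered session schedule plus the seed that produced it."""

    phases: tuple[Phase, ...]
    seed: int
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    @property
    def trials(self) -> tuple[TrialSpec, ...]:
        return tuple(t for ph in self.phases for t in ph.trials)

    def scored_trials(self, task: str | None = None) -> tuple[TrialSpec, ...]:
        """Non-practice trials, optionally restricted to one task."""
        out = [t for t in self.trials if not t.is_practice]
        if task is not None:
            out = [t for t in out if t.task == task]
        return tuple(out)


def _balanced_sides(n: int, rng: np.random.Generator) -> list[str]:
    if n % 2:
        raise ValueError(f"phase trial count must be even to balance sides, got {n}")
    sides = ["right"] * (n // 2) + ["left"] * (n // 2)
    rng.shuffle(sides)
    return sides


def _fore_periods(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n fore-periods in [1, 3.5] s with mean exactly 1.5 s.

    Uniform draws are affinely rescaled about the lower bound toward the
    target mean, re-clipped, and iterated; a final residual is spread over
    the samples with headroom so the mean is exact to float precision.
    """
    values = rng.uniform(FORE_PERIOD_MIN_S, FORE_PERIOD_MAX_S, size=n)
    for _ in range(100):
        mean = values.mean()
        if abs(mean - FORE_PERIOD_MEAN_S) < 1e-13:
            break
        spread = mean - FORE_PERIOD_MIN_S
        if spread <= 0:  # pragma: no cover - degenerate, all at lower bound
            values = np.full(n, FORE_PERIOD_MEAN_S)
            break
        scale = (FORE_PERIOD_MEAN_S - FORE_PERIOD_MIN_S) / spread
        values = FORE_PERIOD_MIN_S + (values - FORE_PERIOD_MIN_S) * scale
        np.clip(values, FORE_PERIOD_MIN_S, FORE_PERIOD_MAX_S, out=values)
    # exact residual correction on samples with headroom
    residual = FORE_PERIOD_MEAN_S * n - values.sum()
    if residual:
        room = (values + residual / n >= FORE_PERIOD_MIN_S) & (
            values + residual / n <= FORE_PERIOD_MAX_S
        )
        idx = np.flatnonzero(room)
        values[idx] += residual / idx.size
    return values


def generate_session_protocol(
    seed: int, geometry: GeometryConfig | None = None
) -> SessionProtocol:
    """Build the standardized session schedule for one seed.

    The same seed always yields the identical protocol, so a whole study
    can share one randomization.
    """
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
    geometry = geometry or GeometryConfig()
    geometry.validate()

    rng = np.random.default_rng(seed)
    phases: list[Phase] = []
    trial_index = 0
    for name, task, n, is_practice, break_after in DEFAULT_PHASE_PLAN:
        sides = _balanced_sides(n, rng)
        fores = _fore_periods(n, rng)
        trials = []
        for side, fore in zip(sides, fores):
            trials.append(
                TrialSpec(
                    trial_index=trial_index,
                    phase=name,
                    task=task,
                    side=side,
                    fore_period_s=float(fore),
                    is_practice=is_practice,
                )
            )
            trial_index += 1
        phases.append(Phase(name, task, is_practice, break_after, tuple(trials)))
    return SessionProtocol(phases=tuple(phases), seed=int(seed), geometry=geometry)


def target_world_geometry(geometry: GeometryConfig) -> dict:
    """World-space (metre) positions and diameters of the stimulus targets.

    The lateral offset of each target is ``distance * tan(eccentricity)``
    and a target subtending ``d`` degrees has world diameter
    ``2 * distance * tan(d / 2)``.
    """
    d = geometry.viewing_distance_m
    if not math.isfinite(d) or d <= 0:
        raise GeometryError(f"viewing_distance_m must be positive, got {d!r}")
    if geometry.target_eccentricity_deg < 0:
        raise GeometryError("target_eccentricity_deg must be non-negative")
    offset = d * math.tan(math.radians(geometry.target_eccentricity_deg))
    diameter = 2.0 * d * math.tan(math.radians(geometry.target_diameter_deg) / 2.0)
    central = 2.0 * d * math.tan(math.radians(geometry.central_target_diameter_deg) / 2.0)
    return {
        "distance_m": d,
        "right_offset_m": offset,
        "left_offset_m": -offset,
        "target_diameter_m": diameter,
        "central_target_diameter_m": central,
    }


PROTOCOL_COLUMNS = ("trial_index", "phase", "task", "side", "fore_period_s", "is_practice")


def write_protocol(protocol: SessionProtocol, path: str | Path) -> None:
    """Write the trial schedule as TSV plus a TOML sidecar with geometry/seed.

    The sidecar is written next to ``path`` with suffix ``.config.toml``.
    """
    path = Path(path)
    lines = ["\t".join(PROTOCOL_COLUMNS)]
    for t in (t for ph in protocol.phases for t in ph.trials):
        lines.append(
            f"{t.trial_index}\t{t.phase}\t{t.task}\t{t.side}\t{t.fore_period_s!r}\t"
            f"{int(t.is_practice)}"
        )
    path.write_text("\n".join(lines) + "\n")

    g = protocol.geometry
    breaks = [ph.name for ph in protocol.phases if ph.break_after]
    sidecar = "\n".join(
        [
            "[protocol]",
            f"seed = {protocol.seed}",
            f'phases = [{", ".join(repr(ph.name) for ph in protocol.phases)}]',
            f'breaks_after = [{", ".join(repr(b) for b in breaks)}]',
            "",
            "[geometry]",
            f"viewing_distance_m = {g.viewing_distance_m!r}",
            f"target_eccentricity_deg = {g.target_eccentricity_deg!r}",
            f"target_diameter_deg = {g.target_diameter_deg!r}",
            f"central_target_diameter_deg = {g.central_target_diameter_deg!r}",
        ]
    )
    path.with_suffix(path.suffix + ".config.toml").write_text(sidecar + "\n")


def read_protocol(path: str | Path) -> SessionProtocol:
    """Read a protocol TSV (and its sidecar, if present) back."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != list(PROTOCOL_COLUMNS):
        raise ValueError(f"{path}: missing or malformed protocol header")

    seed = -1
    geometry = GeometryConfig()
    breaks: set[str] = set()
    sidecar = path.with_suffix(path.suffix + ".config.toml")
    if sidecar.exists():
        with open(sidecar, "rb") as fh:
            cfg = tomllib.load(fh)
        seed = int(cfg.get("protocol", {}).get("seed", -1))
        breaks = set(cfg.get("protocol", {}).get("breaks_after", []))
        gd = cfg.get("geometry", {})
        if gd:
            geometry = GeometryConfig(
                viewing_distance_m=gd["viewing_distance_m"],
                target_eccentricity_deg=gd["target_eccentricity_deg"],
                target_diameter_deg=gd["target_diameter_deg"],
                central_target_diameter_deg=gd["central_target_diameter_deg"],
            )

    trials: list[TrialSpec] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(PROTOCOL_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected {len(PROTOCOL_COLUMNS)} columns")
        trials.append(
            TrialSpec(
                trial_index=int(parts[0]),
                phase=parts[1],
                task=parts[2],
                side=parts[3],
                fore_period_s=float(parts[4]),
                is_practice=bool(int(parts[5])),
            )
        )

    phases: list[Phase] = []
    for name in dict.fromkeys(t.phase for t in trials):
        ph_trials = tuple(t for t in trials if t.phase == name)
        phases.append(
            Phase(
                name=name,
                task=ph_trials[0].task,
                is_practice=ph_trials[0].is_practice,
                break_after=name in breaks,
                trials=ph_trials,
            )
        )
    return SessionProtocol(phases=tuple(phases), seed=seed, geometry=geometry)


def make_task_block(
    task: str,
    n_trials: int,
    seed: int,
    geometry: GeometryConfig | None = None,
    is_practice: bool = False,
) -> SessionProtocol:
    """A single-phase protocol of ``n_trials`` trials of one task.

    Convenience for simulation experiments that exercise one task in
    isolation; sides are balanced and fore-periods follow the same law
    as the full session.
    """
    rng = np.random.default_rng(seed)
    sides = _balanced_sides(n_trials, rng)
    fores = _fore_periods(n_trials, rng)
    trials = tuple(
        TrialSpec(i, f"{task}_block", task, side, float(fore), is_practice)
        for i, (side, fore) in enumerate(zip(sides, fores))
    )
    phase = Phase(f"{task}_block", task, is_practice, False, trials)
    return SessionProtocol(phases=(phase,), seed=int(seed), geometry=geometry or GeometryConfig())
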