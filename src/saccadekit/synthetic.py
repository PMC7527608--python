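"""Synthetic binocular gaze-trace simulator.

Generates eye-sample logs with the statistical and artifactual structure
the analysis pipeline assumes — saccade kinematics on a raised-cosine
position profile, reflexive wrong-direction excursions, direction
errors, Gaussian angle noise, spike noise, validity dropouts, a pupil
series, and a two-clock sampling model with a slow warm-up regime,
dropped frames, and duplicate reads — together with a per-trial ground
truth for parameter-recovery experiments.

Kinematics: a saccade of amplitude ``A`` and peak velocity ``V`` follows
``x(t) = A/2 * (1 - cos(pi t / D))`` with duration ``D = (pi/2) A / V``,
so the analytic maximum velocity equals ``V`` exactly.  Durations are
kept inside a configurable physiological band; when the band clips the
duration the simulator preserves the requested peak velocity and adjusts
the movement amplitude instead (recorded in the ground truth), because
peak velocity is the quantity the detector is asked to recover.

Latencies are drawn from a normal distribution truncated to the task's
search window; the drawn latency is the onset of the (corrective)
saccade's position profile.  The simulated gaze-direction vector is the
exact unit vector of the intended angle, so the angle conversion inverts
it to machine precision before noise injection, and the normalized pupil
position is a linear rescaling of the same trace with its screen x axis
increasing rightward.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .eyedata_io import (
    EYES,
    SAMPLE_COLUMNS,
    TrialEvent,
    _mask_invalid_fields,
    write_events,
    write_samples,
)
from .protocol import SessionProtocol, TrialSpec

__all__ = [
    "TaskSimParams",
    "SamplingConfig",
    "SimConfig",
    "SimulationOutput",
    "saccade_waveform",
    "simulate_trial",
    "simulate_session",
    "simulate_recording",
    "write_simulation",
    "GROUND_TRUTH_COLUMNS",
]

STIMULUS_DURATION_MS = 1000.0

#: fraction of the saccade duration between movement start and the
#: 0.25-of-peak velocity crossing of the raised-cosine profile
#: (velocity ~ sin(pi t / D), so the crossing sits at asin(1/4)/pi * D).
#: The drawn latency is defined at that crossing — the same operational
#: onset the detector reports — so the position profile starts earlier
#: by this fraction of its duration.
ONSET_THRESHOLD_FRACTION = math.asin(0.25) / math.pi

GROUND_TRUTH_COLUMNS = (
    "trial_index",
    "phase",
    "task",
    "side",
    "is_practice",
    "onset_host_time_ms",
    "latency_ms",
    "peak_velocity_dps",
    "direction",
    "is_error",
    "has_reflexive",
    "duration_ms",
    "duration_clipped",
)


@dataclass(frozen=True)
class TaskSimParams:
    """Per-task generative parameters (defaults follow healthy-adult group statistics)."""

    latency_mean_ms: float
    latency_sd_ms: float
    peak_velocity_mean_dps: float
    peak_velocity_sd_dps: float
    reflexive_prob: float
    error_prob: float


@dataclass(frozen=True)
class SamplingConfig:
    """Two-clock sampling model.

    During the warm-up the recording loop is slow: host intervals are
    drawn from ``warmup_interval_ms_range`` (all above the nominal 8.33
    ms).  Afterwards the clock follows either the exact nominal frame
    grid (``steady_model="frame"``) or a polling-loop model with
    intervals from ``loop_interval_ms_range`` (``steady_model="loop"``,
    whose sub-8 ms median makes the stabilization point detectable).
    Frames are dropped with ``drop_prob`` (doubling the device interval)
    and duplicated with ``duplicate_prob`` (re-reads carrying the
    stalled-timestamp bug signature).
    """

    nominal_hz: float = 120.0
    warmup_duration_s: float = 25.0
    warmup_interval_ms_range: tuple[float, float] = (9.0, 14.0)
    steady_model: str = "frame"  # "frame" | "loop"
    loop_interval_ms_range: tuple[float, float] = (6.9, 8.1)
    drop_prob: float = 0.0
    duplicate_prob: float = 0.0

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.nominal_hz

    def validate(self) -> None:
        if self.nominal_hz <= 0:
            raise ValueError("nominal_hz must be positive")
        if self.steady_model not in ("frame", "loop"):
            raise ValueError(f"steady_model must be 'frame' or 'loop', got {self.steady_model!r}")
        for p in (self.drop_prob, self.duplicate_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.warmup_interval_ms_range[0] <= self.frame_period_ms:
            raise ValueError("warm-up intervals must exceed the nominal frame period")


@dataclass(frozen=True)
class SimConfig:
    """All generative knobs of the simulator."""

    pro: TaskSimParams = field(
        default_factory=lambda: TaskSimParams(220.40, 43.16, 357.90, 111.99, 0.014, 0.0024)
    )
    anti: TaskSimParams = field(
        default_factory=lambda: TaskSimParams(343.35, 76.42, 318.79, 116.69, 0.132, 0.0066)
    )
    saccade_amplitude_deg: float = 8.0
    saccade_duration_bounds_ms: tuple[float, float] = (30.0, 100.0)
    peak_velocity_floor_dps: float = 100.0
    reflexive_amplitude_deg: float = 4.0
    reflexive_duration_ms: float = 35.0
    reflexive_gap_ms: float = 80.0
    return_delay_ms: float = 120.0
    angle_noise_sd_deg: float = 0.05
    spike_prob: float = 0.001
    spike_amplitude_deg: float = 30.0
    invalid_prob: float = 0.005
    pupil_mean_mm: float = 4.30
    pupil_sd_mm: float = 0.10
    pupilpos_scale_per_deg: float = 0.015
    host_start_ms: float = 1_600_000_000_000.0
    settle_after_warmup_s: float = 2.0
    sampling: SamplingConfig = field(default_factory=SamplingConfig)

    def task_params(self, task: str) -> TaskSimParams:
        return self.pro if task == "pro" else self.anti

    def validate(self) -> None:
        self.sampling.validate()
        for task in (self.pro, self.anti):
            for p in (task.reflexive_prob, task.error_prob):
                if not (0.0 <= p <= 1.0):
                    raise ValueError("probabilities must lie in [0, 1]")
        if not (0.0 <= self.spike_prob <= 1.0 and 0.0 <= self.invalid_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.saccade_duration_bounds_ms
        if not (0 < lo < hi):
            raise ValueError("saccade_duration_bounds_ms must be an increasing positive pair")

    def noise_free(self) -> "SimConfig":
        """Copy with all stochastic artifacts disabled (kinematics kept)."""
        return replace(
            self,
            angle_noise_sd_deg=0.0,
            spike_prob=0.0,
            invalid_prob=0.0,
            pupil_sd_mm=0.0,
            sampling=replace(self.sampling, drop_prob=0.0, duplicate_prob=0.0),
        )


def _rc01(t_ms: np.ndarray, duration_ms: float) -> np.ndarray:
    """Raised-cosine unit step: 0 before 0, 1 after duration, smooth between."""
    if duration_ms <= 0:
        return (np.asarray(t_ms) >= 0).astype(float)
    u = np.clip(np.asarray(t_ms, dtype=float) / duration_ms, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def saccade_duration_ms(amplitude_deg: float, peak_velocity_dps: float) -> float:
    """Raised-cosine main-sequence duration ``(pi/2) * A / V`` in ms."""
    if peak_velocity_dps <= 0:
        raise ValueError("peak velocity must be positive")
    return (math.pi / 2.0) * abs(amplitude_deg) / peak_velocity_dps * 1000.0


def saccade_waveform(
    amplitude_deg: float,
    peak_velocity_dps: float,
    t_grid_ms,
    onset_ms: float = 0.0,
    duration_bounds_ms: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float, bool]:
    """Angle series of one saccade evaluated on a time grid.

    Returns ``(values_deg, realized_duration_ms, clipped)``.  The
    position profile is a raised cosine whose analytic peak velocity is
    ``peak_velocity_dps`` and whose displacement is ``amplitude_deg``;
    when ``duration_bounds_ms`` clips the derived duration the amplitude
    is kept and the realized peak velocity changes (with a warning).
    """
    t = np.asarray(t_grid_ms, dtype=float)
    if amplitude_deg == 0.0:
        return np.zeros_like(t), 0.0, False
    duration = saccade_duration_ms(amplitude_deg, peak_velocity_dps)
    clipped = False
    if duration_bounds_ms is not None:
        lo, hi = duration_bounds_ms
        if not (lo <= duration <= hi):
            clipped = True
            new_duration = min(max(duration, lo), hi)
            warnings.warn(
                f"saccade duration {duration:.1f} ms outside [{lo}, {hi}] ms; "
                f"clipped to {new_duration:.1f} ms",
                stacklevel=2,
            )
            duration = new_duration
    return amplitude_deg * _rc01(t - onset_ms, duration), duration, clipped


def _truncated_normal(rng, mean, sd, lo, hi, max_tries=10_000):
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise RuntimeError(
        f"truncated normal rejection failed: N({mean}, {sd}) on [{lo}, {hi}]"
    )


def _sample_clock(sampling: SamplingConfig, total_ms: float, rng) -> tuple[np.ndarray, int]:
    """Relative host-clock sample times; returns (times_ms, n_warmup_rows)."""
    warm_end = min(sampling.warmup_duration_s * 1000.0, total_ms)
    warm: list[float] = []
    t = 0.0
    lo_w, hi_w = sampling.warmup_interval_ms_range
    while t < warm_end:
        warm.append(t)
        t += rng.uniform(lo_w, hi_w)
    if sampling.steady_model == "frame":
        h = sampling.frame_period_ms
        n = max(int(math.ceil((total_ms - t) / h)), 0)
        steady = t + np.arange(n) * h
    else:
        lo_l, hi_l = sampling.loop_interval_ms_range
        steady_list: list[float] = []
        while t < total_ms:
            steady_list.append(t)
            t += rng.uniform(lo_l, hi_l)
        steady = np.asarray(steady_list)
    if sampling.drop_prob > 0 and steady.size:
        steady = steady[rng.random(steady.size) >= sampling.drop_prob]
    return np.concatenate([np.asarray(warm), steady]), len(warm)


@dataclass
class _TrialPlan:
    spec: TrialSpec
    onset_rel_ms: float
    next_onset_rel_ms: float
    latency_ms: float
    peak_velocity_dps: float  # signed, of the primary (corrective) saccade
    direction: int
    is_error: bool
    has_reflexive: bool
    duration_ms: float
    duration_clipped: bool
    refl_onset_ms: float | None
    refl_duration_ms: float
    corrective_from: float  # position the primary saccade starts from
    corrective_to: float  # position it lands on


@dataclass
class SimulationOutput:
    """Everything one simulated session produces."""

    samples: pd.DataFrame
    events: list[TrialEvent]
    ground_truth: pd.DataFrame
    config: SimConfig
    seed: int


def _plan_trial(
    spec: TrialSpec,
    onset_rel_ms: float,
    next_onset_rel_ms: float,
    cfg: SimConfig,
    rng,
    force_error: bool | None,
) -> _TrialPlan:
    params = cfg.task_params(spec.task)
    win_lo, win_hi = (100.0, 500.0) if spec.task == "pro" else (125.0, 750.0)
    A = cfg.saccade_amplitude_deg
    lo_d, hi_d = cfg.saccade_duration_bounds_ms

    stim_sign = -1 if spec.side == "right" else 1
    correct_sign = stim_sign if spec.task == "pro" else -stim_sign

    is_error = bool(rng.random() < params.error_prob) if force_error is None else force_error
    executed_sign = -correct_sign if is_error else correct_sign
    has_reflexive = (not is_error) and rng.random() < params.reflexive_prob

    v_mag = _truncated_normal(
        rng, params.peak_velocity_mean_dps, params.peak_velocity_sd_dps,
        cfg.peak_velocity_floor_dps, math.inf,
    )

    refl_from = 0.0
    if has_reflexive:
        refl_from = -executed_sign * cfg.reflexive_amplitude_deg
    corrective_to = executed_sign * A
    amp = abs(corrective_to - refl_from)

    duration = saccade_duration_ms(amp, v_mag)
    clipped = False
    if not (lo_d <= duration <= hi_d):
        # preserve the requested peak velocity; let the amplitude absorb
        # the clip (over-/undershoot) so recovery targets stay meaningful
        clipped = True
        duration = min(max(duration, lo_d), hi_d)
        amp = 2.0 * v_mag * (duration / 1000.0) / math.pi
        corrective_to = refl_from + executed_sign * amp

    latency = _truncated_normal(
        rng, params.latency_mean_ms, params.latency_sd_ms,
        win_lo, min(win_hi, win_hi - duration - 5.0),
    )

    refl_onset = None
    if has_reflexive:
        refl_onset = latency - cfg.reflexive_gap_ms - cfg.reflexive_duration_ms
        if refl_onset <= 0:
            # no room before the stimulus for the excursion: keep the planned
            # corrective amplitude (it matches the drawn duration) from 0
            refl_onset = None
            has_reflexive = False
            corrective_to = corrective_to - refl_from
            refl_from = 0.0

    return _TrialPlan(
        spec=spec,
        onset_rel_ms=onset_rel_ms,
        next_onset_rel_ms=next_onset_rel_ms,
        latency_ms=latency,
        peak_velocity_dps=executed_sign * v_mag,
        direction=executed_sign,
        is_error=is_error,
        has_reflexive=has_reflexive,
        duration_ms=duration,
        duration_clipped=clipped,
        refl_onset_ms=refl_onset,
        refl_duration_ms=cfg.reflexive_duration_ms,
        corrective_from=refl_from,
        corrective_to=corrective_to,
    )


def _trial_angle(plan: _TrialPlan, t_rel: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """True angle series over one trial's segment (times relative to its onset)."""
    pos = np.zeros_like(t_rel)
    start = plan.latency_ms - ONSET_THRESHOLD_FRACTION * plan.duration_ms
    if plan.refl_onset_ms is not None:
        pos += plan.corrective_from * _rc01(t_rel - plan.refl_onset_ms, plan.refl_duration_ms)
    pos += (plan.corrective_to - plan.corrective_from) * _rc01(t_rel - start, plan.duration_ms)
    # return to fixation after stimulus offset, ahead of the next window
    ret_onset = STIMULUS_DURATION_MS + cfg.return_delay_ms
    ret_duration = saccade_duration_ms(abs(plan.corrective_to), abs(plan.peak_velocity_dps))
    pos += (0.0 - plan.corrective_to) * _rc01(t_rel - ret_onset, ret_duration)
    return pos


def simulate_session(
    protocol: SessionProtocol,
    cfg: SimConfig | None = None,
    seed: int = 0,
    forced_error_indices: Sequence[int] | None = None,
) -> SimulationOutput:
    """Simulate a full recording of one session protocol.

    Trials start after the sampling warm-up plus a settle period; each
    trial shows the central target for its fore-period, then the lateral
    stimulus for 1 s with zero gap before the next fore-period.  Events
    are emitted for scored (non-practice) trials only; the ground truth
    has one row per simulated trial.  ``forced_error_indices`` overrides
    the stochastic error draw to inject direction errors at exactly the
    given trial indices (all other trials are then error-free).
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    forced = set(forced_error_indices) if forced_error_indices is not None else None

    # ---- schedule -------------------------------------------------------
    trials = list(protocol.trials)
    t_cursor = cfg.sampling.warmup_duration_s * 1000.0 + cfg.settle_after_warmup_s * 1000.0
    onsets: list[float] = []
    for spec in trials:
        onset = t_cursor + spec.fore_period_s * 1000.0
        onsets.append(onset)
        t_cursor = onset + STIMULUS_DURATION_MS
    total_ms = t_cursor + 500.0

    plans: list[_TrialPlan] = []
    for i, spec in enumerate(trials):
        next_onset = onsets[i + 1] if i + 1 < len(trials) else total_ms
        force = (spec.trial_index in forced) if forced is not None else None
        plans.append(_plan_trial(spec, onsets[i], next_onset, cfg, rng, force))

    # ---- sampling clock -------------------------------------------------
    t_rel, _n_warm = _sample_clock(cfg.sampling, total_ms, rng)
    n = t_rel.size
    h = cfg.sampling.frame_period_ms
    frame_seq = np.floor(t_rel / h + 1e-9).astype(np.int64)
    device_ts = np.rint(t_rel).astype(np.int64)

    # ---- true angle -----------------------------------------------------
    angle = np.zeros(n)
    for plan in plans:
        a = int(np.searchsorted(t_rel, plan.onset_rel_ms, side="left"))
        b = int(np.searchsorted(t_rel, plan.next_onset_rel_ms, side="left"))
        if b > a:
            angle[a:b] = _trial_angle(plan, t_rel[a:b] - plan.onset_rel_ms, cfg)

    # ---- per-eye observation model -------------------------------------
    columns: dict[str, np.ndarray] = {
        "frame_sequence": frame_seq,
        "device_timestamp_ms": device_ts,
        "host_time_ms": cfg.host_start_ms + t_rel,
    }
    for eye in EYES:
        noisy = angle.copy()
        if cfg.angle_noise_sd_deg > 0:
            noisy += rng.normal(0.0, cfg.angle_noise_sd_deg, n)
        if cfg.spike_prob > 0:
            spikes = rng.random(n) < cfg.spike_prob
            noisy[spikes] += rng.choice([-1.0, 1.0], size=int(spikes.sum())) * cfg.spike_amplitude_deg
        theta = np.radians(noisy)

        validity = np.full(n, 31, dtype=np.int64)
        if cfg.invalid_prob > 0:
            bad = rng.random(n) < cfg.invalid_prob
            validity[bad] = 31 - 2 ** rng.integers(0, 5, size=int(bad.sum()))

        pupil = np.full(n, cfg.pupil_mean_mm)
        if cfg.pupil_sd_mm > 0:
            pupil += rng.normal(0.0, cfg.pupil_sd_mm, n)

        origin_x = 31.5 if eye == "right" else -31.5
        columns[f"{eye}_validity"] = validity
        columns[f"{eye}_openness"] = np.ones(n)
        columns[f"{eye}_pupil_diameter_mm"] = pupil
        columns[f"{eye}_pupil_pos_x"] = 0.5 - cfg.pupilpos_scale_per_deg * noisy
        columns[f"{eye}_pupil_pos_y"] = np.full(n, 0.5)
        columns[f"{eye}_gaze_origin_x_mm"] = np.full(n, origin_x)
        columns[f"{eye}_gaze_origin_y_mm"] = np.zeros(n)
        columns[f"{eye}_gaze_origin_z_mm"] = np.full(n, -30.0)
        columns[f"{eye}_gaze_dir_x"] = np.sin(theta)
        columns[f"{eye}_gaze_dir_y"] = np.zeros(n)
        columns[f"{eye}_gaze_dir_z"] = np.cos(theta)

    # ---- duplicate reads (stalled device timestamp signature) ----------
    if cfg.sampling.duplicate_prob > 0 and n > 1:
        dup = np.flatnonzero(rng.random(n - 1) < cfg.sampling.duplicate_prob)
        if dup.size:
            host = columns["host_time_ms"]
            new_host = host[dup] + 0.45 * (host[dup + 1] - host[dup])
            jitter = {
                f"{eye}_pupil_diameter_mm": rng.normal(0.0, 0.01, dup.size) for eye in EYES
            }
            for name in list(columns):
                col = columns[name]
                if name == "host_time_ms":
                    values = new_host
                elif name in jitter:
                    values = col[dup] + jitter[name]
                else:
                    values = col[dup]
                columns[name] = np.insert(col, dup + 1, values)

    samples = pd.DataFrame(columns)[list(SAMPLE_COLUMNS)]
    samples = _mask_invalid_fields(samples)

    # ---- events and ground truth ---------------------------------------
    events = [
        TrialEvent(
            trial_index=plan.spec.trial_index,
            task=plan.spec.task,
            side=plan.spec.side,
            onset_host_time_ms=cfg.host_start_ms + plan.onset_rel_ms,
            offset_host_time_ms=cfg.host_start_ms + plan.onset_rel_ms + STIMULUS_DURATION_MS,
        )
        for plan in plans
        if not plan.spec.is_practice
    ]
    ground_truth = pd.DataFrame(
        [
            {
                "trial_index": plan.spec.trial_index,
                "phase": plan.spec.phase,
                "task": plan.spec.task,
                "side": plan.spec.side,
                "is_practice": plan.spec.is_practice,
                "onset_host_time_ms": cfg.host_start_ms + plan.onset_rel_ms,
                "latency_ms": plan.latency_ms,
                "peak_velocity_dps": plan.peak_velocity_dps,
                "direction": plan.direction,
                "is_error": plan.is_error,
                "has_reflexive": plan.has_reflexive,
                "duration_ms": plan.duration_ms,
                "duration_clipped": plan.duration_clipped,
            }
            for plan in plans
        ],
        columns=list(GROUND_TRUTH_COLUMNS),
    )
    return SimulationOutput(
        samples=samples, events=events, ground_truth=ground_truth, config=cfg, seed=int(seed)
    )


def simulate_trial(
    spec: TrialSpec, cfg: SimConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a single trial (no warm-up); returns (samples, ground-truth row)."""
    from .protocol import Phase

    cfg = cfg or SimConfig()
    cfg = replace(cfg, sampling=replace(cfg.sampling, warmup_duration_s=0.0))
    phase = Phase(spec.phase or f"{spec.task}_single", spec.task, spec.is_practice, False, (spec,))
    protocol = SessionProtocol(phases=(phase,), seed=int(seed))
    out = simulate_session(protocol, cfg, seed=seed)
    return out.samples, out.ground_truth.iloc[0]


def simulate_recording(
    duration_s: float, cfg: SimConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Simulate a trial-free fixation recording (for sampling diagnostics)."""
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    total_ms = duration_s * 1000.0
    t_rel, _ = _sample_clock(cfg.sampling, total_ms, rng)
    n = t_rel.size
    h = cfg.sampling.frame_period_ms
    columns: dict[str, np.ndarray] = {
        "frame_sequence": np.floor(t_rel / h + 1e-9).astype(np.int64),
        "device_timestamp_ms": np.rint(t_rel).astype(np.int64),
        "host_time_ms": cfg.host_start_ms + t_rel,
    }
    angle = (
        rng.normal(0.0, cfg.angle_noise_sd_deg, n)
        if cfg.angle_noise_sd_deg > 0
        else np.zeros(n)
    )
    theta = np.radians(angle)
    for eye in EYES:
        columns[f"{eye}_validity"] = np.full(n, 31, dtype=np.int64)
        columns[f"{eye}_openness"] = np.ones(n)
        columns[f"{eye}_pupil_diameter_mm"] = np.full(n, cfg.pupil_mean_mm) + (
            rng.normal(0.0, cfg.pupil_sd_mm, n) if cfg.pupil_sd_mm > 0 else 0.0
        )
        columns[f"{eye}_pupil_pos_x"] = 0.5 - cfg.pupilpos_scale_per_deg * angle
        columns[f"{eye}_pupil_pos_y"] = np.full(n, 0.5)
        columns[f"{eye}_gaze_origin_x_mm"] = np.full(n, 31.5 if eye == "right" else -31.5)
        columns[f"{eye}_gaze_origin_y_mm"] = np.zeros(n)
        columns[f"{eye}_gaze_origin_z_mm"] = np.full(n, -30.0)
        columns[f"{eye}_gaze_dir_x"] = np.sin(theta)
        columns[f"{eye}_gaze_dir_y"] = np.zeros(n)
        columns[f"{eye}_gaze_dir_z"] = np.cos(theta)
    if cfg.sampling.duplicate_prob > 0 and n > 1:
        dup = np.flatnonzero(rng.random(n - 1) < cfg.sampling.duplicate_prob)
        if dup.size:
            host = columns["host_time_ms"]
            new_host = host[dup] + 0.45 * (host[dup + 1] - host[dup])
            jitter = {
                f"{eye}_pupil_diameter_mm": rng.normal(0.0, 0.01, dup.size) for eye in EYES
            }
            for name in list(columns):
                col = columns[name]
                if name == "host_time_ms":
                    values = new_host
                elif name in jitter:
                    values = col[dup] + jitter[name]
                else:
                    values = col[dup]
                columns[name] = np.insert(col, dup + 1, values)
    return pd.DataFrame(columns)[list(SAMPLE_COLUMNS)]


def write_simulation(out: SimulationOutput, out_dir: str | Path) -> dict[str, Path]:
    """Write samples, events, ground truth, and the resolved config to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": out_dir / "samples.tsv",
        "events": out_dir / "events.tsv",
        "ground_truth": out_dir / "ground_truth.tsv",
        "sim_config": out_dir / "sim_config.json",
    }
    write_samples(out.samples, paths["samples"])
    write_events(out.events, paths["events"])
    out.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    import json

    paths["sim_config"].write_text(
        json.dumps({"seed": out.seed, **asdict(out.config)}, indent=2, default=list) + "\n"
    )
    return paths
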