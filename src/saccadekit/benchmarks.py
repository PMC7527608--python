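"""Parameter-recovery experiments: simulate with known statistics, detect, compare.

These drive the simulator end-to-end through the detector and report how
well the generating latency / peak-velocity statistics are recovered.
Used by the acceptance checks and handy for sanity-checking detector or
simulator changes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import replace

import numpy as np

from .detect import DetectionConfig, analyze_session
from .protocol import make_task_block
from .synthetic import SamplingConfig, SimConfig, simulate_session

__all__ = ["fast_sampling", "recover_latency", "recover_peak_velocity"]


def fast_sampling() -> SamplingConfig:
    """Clean 120 Hz sampling without warm-up, for recovery experiments."""
    return SamplingConfig(warmup_duration_s=0.0, steady_model="frame")


def _low_noise_config(base: SimConfig | None = None) -> SimConfig:
    cfg = base or SimConfig()
    return replace(
        cfg,
        spike_prob=0.0,
        invalid_prob=0.0,
        sampling=fast_sampling(),
        settle_after_warmup_s=1.0,
    )


def recover_latency(
    task: str,
    n_subjects: int = 7,
    trials_per_subject: int = 120,
    seed: int = 0,
    cfg: SimConfig | None = None,
    eyes=("left", "right"),
) -> dict:
    """Simulate subjects performing one task and recover the latency mean.

    Each subject gets an independently randomized trial block; detected
    latencies are pooled over subjects and eyes (gaze signal).  Returns
    generating and detected statistics.
    """
    cfg = _low_noise_config(cfg)
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_subjects)
    latencies: list[float] = []
    true_latencies: list[float] = []
    n_error = 0
    n_trials = 0
    for s in range(n_subjects):
        block = make_task_block(task, trials_per_subject, int(seeds[2 * s]))
        sim = simulate_session(block, cfg, seed=int(seeds[2 * s + 1]))
        results, _ = analyze_session(
            sim.samples, sim.events, DetectionConfig(), eyes=eyes, signal_kinds=("gaze_deg",)
        )
        for r in results:
            n_trials += 1
            if r.unanalyzable or r.case_id == 5 or r.is_error:
                n_error += r.is_error
                continue
            latencies.append(r.latency_ms)
        true_latencies.extend(sim.ground_truth["latency_ms"].tolist())
    detected = np.asarray(latencies)
    return {
        "task": task,
        "n_trials": n_trials,
        "n_detected": detected.size,
        "n_error": n_error,
        "generating_mean_ms": cfg.task_params(task).latency_mean_ms,
        "true_mean_ms": float(np.mean(true_latencies)),
        "detected_mean_ms": float(detected.mean()),
        "detected_sd_ms": float(detected.std(ddof=1)),
    }


def recover_peak_velocity(
    task: str = "pro",
    n_trials: int = 500,
    seed: int = 0,
    cfg: SimConfig | None = None,
) -> dict:
    """Simulate noise-free trials and recover the peak-velocity magnitude mean."""
    cfg = _low_noise_config(cfg)
    cfg = replace(cfg, angle_noise_sd_deg=0.0)
    params = cfg.task_params(task)
    # disable errors/reflexive shapes so every trial carries one clean saccade
    cfg = replace(
        cfg, **{task: dataclasses.replace(params, error_prob=0.0, reflexive_prob=0.0)}
    )
    seeds = np.random.SeedSequence(seed).generate_state(2)
    block = make_task_block(task, n_trials, int(seeds[0]))
    sim = simulate_session(block, cfg, seed=int(seeds[1]))
    results, _ = analyze_session(
        sim.samples, sim.events, DetectionConfig(), eyes=("left",), signal_kinds=("gaze_deg",)
    )
    peaks = np.asarray(
        [abs(r.peak_velocity) for r in results if r.peak_velocity is not None]
    )
    truth = np.abs(sim.ground_truth["peak_velocity_dps"].to_numpy())
    return {
        "task": task,
        "n_trials": n_trials,
        "n_detected": peaks.size,
        "generating_mean_dps": params.peak_velocity_mean_dps,
        "true_mean_dps": float(truth.mean()),
        "detected_mean_dps": float(peaks.mean()),
        "detected_sd_dps": float(peaks.std(ddof=1)),
    }
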