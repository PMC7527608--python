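import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from saccadekit.detect import analyze_session
from saccadekit.preprocess import gaze_angle_deg
from saccadekit.protocol import TrialSpec, make_task_block
from saccadekit.synthetic import (
    SamplingConfig,
    SimConfig,
    TaskSimParams,
    saccade_duration_ms,
    saccade_waveform,
    simulate_session,
    simulate_trial,
    write_simulation,
)
from saccadekit.eyedata_io import read_events, read_samples_frame


class TestWaveform:
    def test_duration_closed_form(self):
        # (pi/2) * 8 / 357.9 ~ 35.1 ms
        assert saccade_duration_ms(8.0, 357.9) == pytest.approx(35.115, abs=0.01)

    def test_zero_amplitude_flat(self):
        t = np.linspace(-50, 150, 500)
        values, duration, clipped = saccade_waveform(0.0, 400.0, t)
        assert not values.any() and duration == 0.0 and not clipped

    def test_displacement_equals_amplitude(self):
        t = np.linspace(-20.0, 200.0, 2000)
        values, duration, _ = saccade_waveform(-8.0, 360.0, t)
        assert values[0] == 0.0
        assert values[-1] == pytest.approx(-8.0, abs=1e-12)

    def test_dense_grid_max_derivative_matches_peak_within_1pct(self):
        t = np.arange(-10.0, 120.0, 1.0e-1)  # 10 kHz grid
        for peak in (200.0, 357.9, 500.0):
            values, _, _ = saccade_waveform(8.0, peak, t)
            v = np.diff(values) / np.diff(t) * 1000.0
            assert v.max() == pytest.approx(peak, rel=0.01)

    def test_duration_clip_warns_and_flags(self):
        t = np.linspace(0, 200, 100)
        with pytest.warns(UserWarning, match="clipped"):
            _, duration, clipped = saccade_waveform(8.0, 800.0, t, duration_bounds_ms=(30, 100))
        assert clipped and duration == 30.0


class TestDeterminism:
    def test_same_seed_identical_logs(self, low_noise_config):
        block = make_task_block("pro", 6, 1)
        a = simulate_session(block, low_noise_config, seed=5)
        b = simulate_session(block, low_noise_config, seed=5)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)
        assert a.events == b.events

    def test_different_seed_differs(self, low_noise_config):
        block = make_task_block("pro", 6, 1)
        a = simulate_session(block, low_noise_config, seed=5)
        b = simulate_session(block, low_noise_config, seed=6)
        assert not a.samples["left_gaze_dir_x"].equals(b.samples["left_gaze_dir_x"])


class TestInversion:
    def test_gaze_direction_inverts_to_intended_angle(self, noise_free_config):
        """Angle reconstruction and the pupil-position rescaling agree to 1e-9."""
        block = make_task_block("pro", 4, 2)
        sim = simulate_session(block, noise_free_config, seed=3)
        gd_x = sim.samples["left_gaze_dir_x"].to_numpy()
        gd_z = sim.samples["left_gaze_dir_z"].to_numpy()
        angle = gaze_angle_deg(gd_x, gd_z)
        px = sim.samples["left_pupil_pos_x"].to_numpy()
        angle_from_pupil = (0.5 - px) / noise_free_config.pupilpos_scale_per_deg
        np.testing.assert_allclose(angle, angle_from_pupil, atol=1e-9)
        # gaze_dir is a unit vector with components in [-1, 1]
        norm = gd_x**2 + sim.samples["left_gaze_dir_y"].to_numpy() ** 2 + gd_z**2
        np.testing.assert_allclose(norm, 1.0, atol=1e-12)


class TestTrialRecovery:
    def test_noise_free_latency_within_one_sample(self, noise_free_config):
        block = make_task_block("pro", 30, 4)
        cfg = replace(
            noise_free_config,
            pro=replace(noise_free_config.pro, error_prob=0.0, reflexive_prob=0.0),
        )
        sim = simulate_session(block, cfg, seed=7)
        results, _ = analyze_session(
            sim.samples, sim.events, eyes=("left",), signal_kinds=("gaze_deg",)
        )
        truth = sim.ground_truth.set_index("trial_index")
        assert len(results) == 30
        for r in results:
            assert not r.is_error and not r.unanalyzable
            t = truth.loc[r.trial_index]
            assert r.latency_ms == pytest.approx(t["latency_ms"], abs=1000.0 / 120.0)
            assert math.copysign(1, r.peak_velocity) == t["direction"]

    def test_forced_errors_detected_exactly(self, noise_free_config):
        block = make_task_block("pro", 20, 5)
        cfg = replace(
            noise_free_config, pro=replace(noise_free_config.pro, reflexive_prob=0.0)
        )
        sim = simulate_session(block, cfg, seed=8, forced_error_indices=[3, 11])
        assert sim.ground_truth["is_error"].sum() == 2
        results, _ = analyze_session(
            sim.samples, sim.events, eyes=("left",), signal_kinds=("gaze_deg",)
        )
        detected = {r.trial_index for r in results if r.is_error}
        assert detected == {3, 11}

    def test_reflexive_prob_one_all_flagged(self, noise_free_config):
        # latencies high enough that the 4 deg excursion fits the window
        anti = TaskSimParams(
            latency_mean_ms=420.0, latency_sd_ms=30.0,
            peak_velocity_mean_dps=318.79, peak_velocity_sd_dps=116.69,
            reflexive_prob=1.0, error_prob=0.0,
        )
        cfg = replace(noise_free_config, anti=anti)
        block = make_task_block("anti", 20, 6)
        sim = simulate_session(block, cfg, seed=9)
        assert sim.ground_truth["has_reflexive"].all()
        results, _ = analyze_session(
            sim.samples, sim.events, eyes=("left",), signal_kinds=("gaze_deg",)
        )
        assert all(r.has_reflexive_onset for r in results)

    def test_invalid_prob_one_unanalyzable(self, noise_free_config):
        cfg = replace(noise_free_config, invalid_prob=1.0)
        block = make_task_block("pro", 4, 7)
        sim = simulate_session(block, cfg, seed=10)
        with pytest.warns(UserWarning, match="unanalyzable"):
            results, metrics = analyze_session(
                sim.samples, sim.events, eyes=("left",), signal_kinds=("gaze_deg",)
            )
        assert all(r.unanalyzable for r in results)
        assert all(m.n_unanalyzable == m.n_trials for m in metrics)


class TestSessionStructure:
    def test_ground_truth_row_per_trial(self, small_session, small_protocol):
        assert len(small_session.ground_truth) == len(small_protocol.trials)

    def test_events_exclude_practice(self, noise_free_config):
        from saccadekit.protocol import generate_session_protocol

        proto = generate_session_protocol(1)
        cfg = replace(noise_free_config, sampling=SamplingConfig(warmup_duration_s=0.0))
        sim = simulate_session(proto, cfg, seed=11)
        assert len(sim.events) == 240
        assert len(sim.ground_truth) == 254  # 240 scored + 14 practice
        assert sum(e.task == "pro" for e in sim.events) == 120

    def test_simulate_trial_single(self, noise_free_config):
        spec = TrialSpec(0, "pro_single", "pro", "right", 1.2, False)
        samples, truth = simulate_trial(spec, noise_free_config, seed=12)
        assert truth["side"] == "right"
        assert truth["direction"] == -1
        assert len(samples) > 200

    def test_duration_clipping_recorded(self, noise_free_config):
        pro = TaskSimParams(220.4, 43.16, 700.0, 1.0, 0.0, 0.0)  # too fast for 8 deg
        cfg = replace(noise_free_config, pro=pro)
        block = make_task_block("pro", 4, 8)
        sim = simulate_session(block, cfg, seed=13)
        gt = sim.ground_truth
        assert gt["duration_clipped"].all()
        assert np.allclose(gt["duration_ms"], 30.0)
        # peak velocity preserved by amplitude adjustment (draws have sd 1)
        assert np.allclose(np.abs(gt["peak_velocity_dps"]), 700.0, atol=5.0)

    def test_write_simulation_roundtrip(self, tmp_path, small_session):
        paths = write_simulation(small_session, tmp_path)
        frame = read_samples_frame(paths["samples"])
        events = read_events(paths["events"])
        assert len(frame) == len(small_session.samples)
        assert events == small_session.events
        gt = pd.read_csv(paths["ground_truth"], sep="\t")
        assert len(gt) == len(small_session.ground_truth)


class TestPupilAndValidity:
    def test_pupil_series_near_configured_mean(self, small_session, low_noise_config):
        pupil = small_session.samples["left_pupil_diameter_mm"]
        assert pupil.mean() == pytest.approx(low_noise_config.pupil_mean_mm, abs=0.05)

    def test_validity_dropouts_rate(self, noise_free_config):
        cfg = replace(noise_free_config, invalid_prob=0.1)
        block = make_task_block("pro", 6, 9)
        sim = simulate_session(block, cfg, seed=14)
        validity = sim.samples["left_validity"].to_numpy()
        frac = np.mean(validity != 31)
        assert frac == pytest.approx(0.1, rel=0.25)
        # invalid fields masked to NaN consistently with their bit
        bad = sim.samples[sim.samples["left_validity"] == 15]  # pupil position bit unset
        if len(bad):
            assert bad["left_pupil_pos_x"].isna().all()
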