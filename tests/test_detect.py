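import numpy as np
import pytest

from saccadekit.detect import (
    DetectionConfig,
    TrialResult,
    classify_and_detect,
    detect_pupilpos_variant,
    error_rate,
    expected_sign,
    reflexive_flag,
)
from _utils import FRAME_MS, brute_force_classify, make_window


class TestExpectedSign:
    @pytest.mark.parametrize(
        "task,side,kind,sign",
        [
            ("pro", "right", "gaze_deg", -1),
            ("pro", "left", "gaze_deg", 1),
            ("anti", "right", "gaze_deg", 1),
            ("anti", "left", "gaze_deg", -1),
            ("pro", "right", "pupil_pos_x", 1),
            ("anti", "right", "pupil_pos_x", -1),
        ],
    )
    def test_sign_table(self, task, side, kind, sign):
        assert expected_sign(task, side, kind) == sign


class TestCases:
    def test_case1_pro_right(self):
        win = make_window([(200.0, -8.0, 40.0)], task="pro")
        res = classify_and_detect(win, "right", "pro")
        assert res.case_id == 1
        assert not res.is_error
        assert res.latency_ms == pytest.approx(200.0, abs=FRAME_MS)
        assert res.peak_velocity < 0

    def test_case1_side_flip_is_error(self):
        win = make_window([(200.0, -8.0, 40.0)], task="pro")
        res = classify_and_detect(win, "left", "pro")
        assert res.is_error
        assert res.peak_velocity < 0  # first supra-threshold peak reported

    def test_case2_with_return_movement(self):
        win = make_window([(200.0, -8.0, 40.0), (380.0, 8.0, 40.0)], task="pro")
        res = classify_and_detect(win, "right", "pro")
        assert res.case_id == 2
        assert not res.is_error
        assert res.latency_ms == pytest.approx(200.0, abs=FRAME_MS)

    def test_case3_reflexive_then_corrective(self):
        # anti trial, right stimulus: reflexive excursion right (-4), then
        # corrective saccade to +8
        win = make_window([(210.0, -4.0, 35.0), (325.0, 12.0, 55.0)], task="anti")
        res = classify_and_detect(win, "right", "anti")
        assert res.case_id == 3
        assert not res.is_error
        assert res.has_reflexive_onset
        # latency measured on the corrective movement, not the excursion
        assert res.latency_ms == pytest.approx(325.0, abs=2 * FRAME_MS)
        assert res.peak_velocity > 0

    def test_case4_reflexive_corrective_return(self):
        win = make_window(
            [(210.0, -4.0, 35.0), (325.0, 12.0, 55.0), (600.0, -8.0, 40.0)], task="anti"
        )
        res = classify_and_detect(win, "right", "anti")
        assert res.case_id == 4
        assert res.has_reflexive_onset and not res.is_error

    def test_case5_flat_trace(self):
        win = make_window([(200.0, 0.2, 40.0)], task="pro")
        res = classify_and_detect(win, "right", "pro")
        assert res.case_id == 5
        assert res.latency_ms is None and res.peak_velocity is None
        assert res.is_error  # task not performed

    def test_case5_exact_zero_velocity(self):
        win = make_window([], task="pro")
        res = classify_and_detect(win, "right", "pro")
        assert res.case_id == 5

    def test_anti_sign_inversion(self):
        # anti, left stimulus: correct movement is rightward (negative)
        win = make_window([(300.0, -8.0, 40.0)], task="anti")
        assert not classify_and_detect(win, "left", "anti").is_error
        assert classify_and_detect(win, "right", "anti").is_error

    def test_min_samples_guard(self):
        win = make_window([(200.0, -8.0, 40.0)], task="pro")
        cfg = DetectionConfig(min_samples=1000)
        assert classify_and_detect(win, "right", "pro", cfg).unanalyzable

    def test_determinism(self):
        win1 = make_window([(210.0, -4.0, 35.0), (325.0, 12.0, 55.0)], task="anti")
        win2 = make_window([(210.0, -4.0, 35.0), (325.0, 12.0, 55.0)], task="anti")
        assert classify_and_detect(win1, "right", "anti") == classify_and_detect(
            win2, "right", "anti"
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(onset_threshold_norm=0.6, peak_threshold_norm=0.5)


class TestPeakVelocityValue:
    def test_recovers_analytic_peak_within_5pct(self):
        for peak_v, duration in [(360.0, 35.0), (250.0, 50.0), (500.0, 30.0)]:
            amp = 2.0 * peak_v * (duration / 1000.0) / np.pi
            win = make_window([(200.0, amp, duration)], task="pro", phase=3.1)
            res = classify_and_detect(win, "left", "pro")
            assert abs(res.peak_velocity) == pytest.approx(peak_v, rel=0.05)


class TestReflexiveFlag:
    def test_monotone_correct_saccade_not_flagged(self):
        win = make_window([(200.0, -8.0, 40.0)], task="pro")
        assert not reflexive_flag(win, "right", "pro")

    def test_4deg_wrong_direction_excursion_flagged(self):
        win = make_window([(200.0, -4.0, 35.0), (320.0, 12.0, 55.0)], task="anti")
        assert reflexive_flag(win, "right", "anti")

    def test_2deg_excursion_below_threshold(self):
        win = make_window([(200.0, -2.0, 35.0), (320.0, 10.0, 55.0)], task="anti")
        assert not reflexive_flag(win, "right", "anti")

    def test_rule_requires_gaze_signal(self):
        win = make_window([(200.0, 0.05, 35.0)], task="anti", signal_kind="pupil_pos_x")
        with pytest.raises(ValueError):
            reflexive_flag(win, "right", "anti")


class TestPupilPosVariant:
    @staticmethod
    def _paired_windows(error=False):
        """The same movement encoded as gaze degrees and pupil position."""
        sign = 1 if error else -1  # right target, pro: correct is negative
        gaze = make_window([(200.0, sign * 8.0, 40.0)], task="pro")
        pupil = make_window(
            [(200.0, -0.015 * sign * 8.0, 40.0)], task="pro", signal_kind="pupil_pos_x"
        )
        return gaze, pupil

    def test_equal_error_classification(self):
        for error in (False, True):
            gaze, pupil = self._paired_windows(error)
            rg = classify_and_detect(gaze, "right", "pro")
            rp = detect_pupilpos_variant(pupil, "right", "pro")
            assert rg.is_error == rp.is_error == error

    def test_latency_agreement_within_two_samples(self):
        gaze, pupil = self._paired_windows()
        rg = classify_and_detect(gaze, "right", "pro")
        rp = detect_pupilpos_variant(pupil, "right", "pro")
        assert rp.latency_ms == pytest.approx(rg.latency_ms, abs=2 * FRAME_MS)

    def test_no_peak_velocity_reported(self):
        _, pupil = self._paired_windows()
        assert detect_pupilpos_variant(pupil, "right", "pro").peak_velocity is None

    def test_flat_pupil_trace_case5(self):
        pupil = make_window([(200.0, 0.0005, 40.0)], task="pro", signal_kind="pupil_pos_x")
        assert detect_pupilpos_variant(pupil, "right", "pro").case_id == 5

    def test_wrong_signal_kind_rejected(self):
        gaze, _ = self._paired_windows()
        with pytest.raises(ValueError):
            detect_pupilpos_variant(gaze, "right", "pro")


class TestErrorRate:
    @staticmethod
    def _results(n, n_error, n_unanalyzable=0):
        out = []
        for i in range(n):
            out.append(
                TrialResult(
                    trial_index=i, eye="left", signal_kind="gaze_deg", task="pro",
                    side="right", case_id=1, latency_ms=200.0, peak_velocity=-300.0,
                    is_error=i < n_error, unanalyzable=n - i <= n_unanalyzable,
                )
            )
        return out

    def test_zero_errors(self):
        assert error_rate(self._results(120, 0)) == 0.0

    def test_three_of_120_is_2_5pct(self):
        assert error_rate(self._results(120, 3)) == pytest.approx(2.5)

    def test_unanalyzable_excluded_from_denominator(self):
        assert error_rate(self._results(110, 10, n_unanalyzable=10)) == pytest.approx(10.0)

    def test_no_analyzed_trials_raises(self):
        with pytest.raises(ValueError):
            error_rate(self._results(5, 0, n_unanalyzable=5))


class TestBruteForceOracle:
    """Case assignment must match a literal rule evaluation over all extrema."""

    @staticmethod
    def _random_window(rng):
        n_moves = int(rng.integers(1, 4))
        segments = []
        t = 160.0
        for _ in range(n_moves):
            delta = float(rng.uniform(1.5, 10.0)) * (1 if rng.random() < 0.5 else -1)
            duration = float(rng.uniform(30.0, 90.0))
            segments.append((t, delta, duration))
            t += duration + float(rng.uniform(20.0, 80.0))
        return make_window(segments, task="pro", window=(100.0, 100.0 + 59 * FRAME_MS))

    def test_agreement_on_400_random_windows(self, rng):
        cfg = DetectionConfig()
        for _ in range(400):
            win = self._random_window(rng)
            assert win.n_samples <= 60
            side = "right" if rng.random() < 0.5 else "left"
            got = classify_and_detect(win, side, "pro", cfg)
            want = brute_force_classify(
                win.values, win.velocity, expected_sign("pro", side), cfg.no_move_deg
            )
            assert got.case_id == want["case_id"]
            assert got.is_error == want["is_error"]
            if want["onset"] is not None:
                assert got.latency_ms == pytest.approx(
                    win.velocity_times_ms[want["onset"]], abs=1e-9
                )
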