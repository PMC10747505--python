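"""Event detectors against constructed traces, brute-force scan
oracles, threshold semantics, and ground-truth recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import closed_form_onset_frame, make_row
from handover import events, synth
from handover.events import (
    UndefinedEventError, detect_approach_onset, detect_contact_onset,
    detect_liftoff, detect_transfer, identify_opposing_finger,
    lift_delay_distance, lift_delay_force,
)


# --- independent linear-scan oracles ---------------------------------------

def scan_contact(x, baseline, thr):
    for i, v in enumerate(x):
        if abs(v - baseline) > thr:
            return i
    return None


def scan_liftoff(z, baseline, thr):
    for i, v in enumerate(z):
        if v - baseline >= thr:
            return i
    return None


def scan_argmin_latest(x):
    m = min(x)
    return max(i for i, v in enumerate(x) if v == m)


class TestContactOnset:
    def test_step_above_threshold(self):
        x = np.zeros(1000)
        x[300:] = 0.08
        assert detect_contact_onset(x) == 300

    def test_step_exactly_at_threshold_not_detected(self):
        # the criterion is a change of *more than* 0.07 N, strictly
        x = np.zeros(1000)
        x[300:] = 0.07
        assert detect_contact_onset(x) is None

    def test_all_zero_forces_undefined(self):
        assert detect_contact_onset(np.zeros(500)) is None

    def test_deviation_is_relative_to_baseline(self):
        x = np.full(1000, 1.5)  # biased channel at rest
        x[600:] = 1.5 + 0.08
        assert detect_contact_onset(x) == 600

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.normal(0, 0.02, 400))
        x[:50] = 0.0
        got = detect_contact_onset(x)
        assert got == scan_contact(x, np.median(x[:50]), 0.07)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        x = np.abs(np.cumsum(rng.normal(0, 0.05, 300)))
        x[:50] = 0
        frames = [detect_contact_onset(x, thr) for thr in (0.05, 0.07, 0.2, 1.0)]
        cleaned = [f if f is not None else np.inf for f in frames]
        assert cleaned == sorted(cleaned)


class TestLiftoff:
    def test_ten_mm_per_second_rise(self):
        # 0.1 mm/frame: 2 mm reached (inclusive) exactly 20 frames in
        z = np.zeros(1000)
        z[500:] = 0.1 * np.arange(500)
        assert detect_liftoff(z, baseline=0.0) == 520

    def test_constant_height_undefined(self):
        assert detect_liftoff(np.full(300, 55.0), baseline=55.0) is None

    def test_inclusive_threshold(self):
        z = np.zeros(100)
        z[60:] = 2.0  # exactly 2 mm counts ("at least")
        assert detect_liftoff(z, baseline=0.0) == 60

    def test_monotone_in_threshold(self):
        z = np.concatenate([np.zeros(50), np.linspace(0, 30, 100)])
        f2 = detect_liftoff(z, 0.0, threshold_mm=2)
        f5 = detect_liftoff(z, 0.0, threshold_mm=5)
        assert f2 <= f5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        z = np.cumsum(rng.normal(0.05, 0.3, 300))
        assert detect_liftoff(z, baseline=0.0) == scan_liftoff(z, 0.0, 2.0)


class TestTransfer:
    def test_receiver_ramp_first_strict_crossing(self):
        n = 1500
        g = {"g_s1_fx": np.zeros(n)}
        g["g_s1_fx"][700:] = 3.0
        r = np.zeros(n)
        r[800:815] = np.linspace(0, 2, 15, endpoint=False)  # 0 -> 2 N over 150 ms
        r[815:] = 2.0
        start, release = detect_transfer(g, r.reshape(-1, 1))
        assert start == scan_contact(r, 0.0, 0.07)

    def test_giver_never_releases(self):
        n = 1000
        g = {"g_s1_fx": np.full(n, 3.0)}
        g["g_s1_fx"][:100] = 0
        r = np.zeros(n)
        r[500:] = 2.0
        start, release = detect_transfer(g, r.reshape(-1, 1))
        assert start == 500 and release is None

    def test_release_requires_sustained_subthreshold(self):
        n = 1000
        gx = np.zeros(n)
        gx[100:600] = 3.0
        gx[605:610] = 3.0  # 50 ms flicker back up
        g = {"g_s1_fx": gx}
        r = np.zeros(n)
        r[550:] = 2.0
        start, release = detect_transfer(g, r.reshape(-1, 1))
        assert start == 550
        assert release == 610  # not 600: the dip before the flicker is < 100 ms

    def test_no_receiver_contact_undefined(self):
        g = {"g_s1_fx": np.ones(500)}
        start, release = detect_transfer(g, np.zeros((500, 1)))
        assert start is None and release is None


class TestApproachOnset:
    def test_min_jerk_closed_form(self):
        t0, T = 100, 50  # 500 ms reach
        tau = np.clip((np.arange(400) - t0) / T, 0, 1)
        speed = 30 * tau**2 * (1 - tau) ** 2
        got = detect_approach_onset(speed)
        crossing = synth.min_jerk_speed_crossing_tau(0.05)
        expected = t0 + int(np.floor(crossing * T)) + 1
        assert got == expected
        assert abs(got - t0) * 10 <= 30  # within 30 ms of true start

    def test_stationary_wrist_undefined(self):
        assert detect_approach_onset(np.zeros(200)) is None

    def test_false_start_skipped(self):
        # a 30 ms blip above threshold, then the real sustained reach
        speed = np.zeros(500)
        speed[100:103] = 10.0
        speed[200:300] = np.linspace(0, 100, 100)
        got = detect_approach_onset(speed)
        assert got > 103
        thr = 0.05 * speed.max()
        first_sustained = next(
            i for i in range(len(speed) - 5)
            if all(speed[i + k] > thr for k in range(5))
        )
        assert got == first_sustained


class TestFingerAlgorithms:
    def test_lower_sd_wins(self):
        rng = np.random.default_rng(0)
        idx = 50 + rng.normal(0, 0.5, 300)
        mid = 52 + rng.normal(0, 2.0, 300)
        finger, reliable = identify_opposing_finger(idx, mid, 0, 300)
        assert finger == "index" and reliable

    def test_short_window_flagged_unreliable(self):
        idx, mid = np.ones(50), np.full(50, 2.0)
        _, reliable = identify_opposing_finger(idx, mid, 10, 15)
        assert not reliable

    def test_lift_delay_force_arithmetic(self):
        assert lift_delay_force(300, 330) == 300.0
        assert lift_delay_force(300, 300) == 0.0
        with pytest.raises(UndefinedEventError):
            lift_delay_force(None, 330)

    def test_lift_delay_distance_argmin(self):
        d = np.full(400, 60.0)
        d[200:331] = 55.0
        d[310] = 50.0  # unique minimum at 310
        delay, closure = lift_delay_distance(d, approach_onset_frame=100, liftoff_frame=330)
        assert (delay, closure) == (200.0, 310)

    def test_monotone_decreasing_gives_zero(self):
        d = np.linspace(80, 50, 400)
        delay, closure = lift_delay_distance(d, 100, 330)
        assert delay == 0.0 and closure == 330

    def test_tie_breaks_to_latest_frame(self):
        d = np.full(400, 60.0)
        d[[250, 280, 300]] = 50.0
        delay, closure = lift_delay_distance(d, 100, 330)
        assert closure == 300 == scan_argmin_latest(list(d[100:331])) + 100
        assert delay == 300.0


class TestGroundTruthRecovery:
    def test_noiseless_detectors_frame_exact(self):
        """All five detected events within one frame of their noiseless
        targets (lift-off triggers one frame after motion onset because
        the object must first rise 2 mm)."""
        for seed in range(20):
            rec, truth = synth.simulate_trial(make_row(), synth.NOISELESS, seed=seed)
            ev = events.detect_events(rec)
            assert ev.contact_frame == truth.true_contact_frame
            assert abs(ev.liftoff_frame - truth.true_liftoff_frame) <= 1
            assert ev.transfer_start_frame == truth.true_transfer_start_frame
            assert ev.release_frame == truth.true_release_frame
            assert abs(ev.approach_onset_frame - closed_form_onset_frame(truth)) <= 1

    def test_noiseless_distance_delay_matches_truth(self):
        for seed in range(10):
            rec, truth = synth.simulate_trial(make_row(), synth.NOISELESS, seed=100 + seed)
            rcd = events.analyze_trial(rec)
            assert rcd.opposing_finger == truth.true_opposing_finger
            assert abs(rcd.delay_force_ms - truth.delay_force_ms) <= 10
            assert abs(rcd.delay_distance_ms - truth.delay_distance_ms) <= 10

    def test_default_noise_finger_recovery(self, small_cohort):
        rate = (small_cohort.opposing_finger == small_cohort.true_opposing_finger).mean()
        assert rate >= 0.95

    def test_delays_nonnegative_and_finite(self, small_cohort):
        for col in ("delay_force_ms", "delay_distance_ms"):
            assert np.isfinite(small_cohort[col]).all()
            assert (small_cohort[col] >= 0).all()

    def test_undefined_inputs_propagate(self, noiseless_trial):
        rec, _ = noiseless_trial
        ev = events.HandoverEvents()  # nothing detected
        with pytest.raises(UndefinedEventError):
            events.analyze_trial(rec, ev)
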