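"""Driving-metric tests: filters, SA, SDLP, obstacle measures, collisions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glaucodrive.course import CourseSpec
from glaucodrive.driving_metrics import (
    SAMPLE_RATE_HZ, SessionTrace, detect_collisions, lat_dto, long_dto,
    lowpass, sdlp, session_driving_metrics, steering_activity,
)

FS = SAMPLE_RATE_HZ


def sine(freq_hz, amp, duration_s=60.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return t, amp * np.sin(2 * np.pi * freq_hz * t)


def make_trace(y=None, steer=None, s=None, n=None, session="S3"):
    if n is None:
        n = len(y) if y is not None else len(steer)
    t = np.arange(n) / FS
    v = 100 / 3.6
    return SessionTrace(
        session_id=session,
        t=t,
        s_m=s if s is not None else v * t,
        y_m=y if y is not None else np.zeros(n),
        steer_deg=steer if steer is not None else np.zeros(n),
    )


class TestLowpass:
    def test_passband_amplitude_preserved(self):
        t, x = sine(0.1, 1.0)
        y = lowpass(x, 2.0)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("cutoff", [0.5, 2.0, 20.0])
    def test_gain_at_cutoff_is_half(self, cutoff):
        # forward-backward 2nd-order Butterworth: |H|^2 at f_c = 0.5.
        # Amplitude estimated from the RMS (robust to the coarse 3
        # samples/period at the 20 Hz cutoff).
        t, x = sine(cutoff, 1.0, duration_s=240.0)
        y = lowpass(x, cutoff)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        gain = np.sqrt(2.0) * np.std(y[mid])
        assert gain == pytest.approx(0.50, abs=0.02)

    def test_dc_unchanged(self):
        x = np.full(6000, 3.7)
        assert np.allclose(lowpass(x, 2.0), 3.7)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            lowpass(np.zeros(10), 2.0)


class TestSteeringActivity:
    def test_sinusoid_closed_form(self):
        # θ = 10 sin(2π 0.3 t): mean |θ'| = A·ω·(2/π) = 4·A·f = 12 deg/s
        t, steer = sine(0.3, 10.0, duration_s=120.0)
        sa = steering_activity(steer, np.ones_like(steer, dtype=bool))
        assert sa == pytest.approx(12.0, abs=0.1)

    def test_constant_angle_zero(self):
        sa = steering_activity(np.full(6000, 5.0), np.ones(6000, dtype=bool))
        assert sa == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_amplitude(self):
        t, s1 = sine(0.4, 3.0, duration_s=90.0)
        _, s2 = sine(0.4, 6.0, duration_s=90.0)
        mask = np.ones_like(s1, dtype=bool)
        assert steering_activity(s2, mask) == pytest.approx(
            2 * steering_activity(s1, mask), rel=1e-6)

    def test_sign_flip_invariant(self):
        rng = np.random.default_rng(3)
        steer = np.cumsum(rng.standard_normal(6000)) * 0.01
        mask = np.ones(6000, dtype=bool)
        assert steering_activity(-steer, mask) == pytest.approx(
            steering_activity(steer, mask))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            steering_activity(np.zeros(6000), np.zeros(6000, dtype=bool))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_low_cutoff_never_exceeds_high_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        steer = np.cumsum(rng.standard_normal(4000)) * 0.02
        mask = np.ones(4000, dtype=bool)
        sa_low = steering_activity(lowpass(steer, 0.5), mask)
        sa_high = steering_activity(lowpass(steer, 2.0), mask)
        assert sa_low <= sa_high + 1e-9


class TestSdlp:
    def test_sinusoid_rms(self):
        # whole periods: SD of A·sin = A/√2
        t, y = sine(0.25, 0.5, duration_s=120.0)
        val = sdlp(y, np.ones_like(y, dtype=bool))
        assert val == pytest.approx(0.5 / np.sqrt(2), rel=0.01)

    def test_constant_zero(self):
        assert sdlp(np.full(1000, 2.0), np.ones(1000, dtype=bool)) == 0.0

    def test_hand_computed_sample_sd(self):
        assert sdlp(np.array([0.1, 0.2, 0.3]),
                    np.ones(3, dtype=bool)) == pytest.approx(0.1)

    def test_shift_invariant(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(2000)
        mask = np.ones(2000, dtype=bool)
        assert sdlp(y + 123.4, mask) == pytest.approx(sdlp(y, mask))


class TestLongDtO:
    def test_simple_crossing_distance(self):
        # ramp crossing y=1.8 at exactly s=6045, obstacle at 6095
        s = np.linspace(5940, 6100, 2000)
        y = np.where(s < 6025, 0.0, np.where(s > 6065, 3.6,
                     (s - 6025) / 40 * 3.6))
        tr = make_trace(y=y, s=s, n=len(s))
        got = long_dto(tr, 6095.0)
        assert got == pytest.approx(6095 - 6045, abs=0.2)

    def test_stays_right_lane_undefined(self):
        s = np.linspace(5940, 6100, 1000)
        tr = make_trace(y=np.zeros_like(s), s=s, n=len(s))
        assert long_dto(tr, 6095.0) is None

    def test_weave_uses_last_committed_crossing(self):
        # crosses at 5970, dips back below, recrosses at 6045 and commits
        s = np.linspace(5940, 6100, 4000)
        y = np.zeros_like(s)
        y[(s > 5960) & (s <= 6000)] = np.interp(
            s[(s > 5960) & (s <= 6000)], [5960, 5970, 5990, 6000],
            [0.0, 2.2, 2.2, 0.5])
        after = s > 6035
        y[after] = np.minimum((s[after] - 6035) / 20 * 3.6, 3.6)
        tr = make_trace(y=y, s=s, n=len(s))
        got = long_dto(tr, 6095.0)
        # committed crossing at y=1.8 on the final ramp: s = 6035 + 10 = 6045
        assert got == pytest.approx(50.0, abs=0.3)


class TestLatDtO:
    def test_absolute_lateral_offset(self):
        n = 1000
        tr = make_trace(y=np.full(n, 3.07), s=np.linspace(0, 500, n), n=n)
        assert lat_dto(tr, 250.0) == pytest.approx(3.07)

    def test_zero_offset(self):
        n = 1000
        tr = make_trace(y=np.zeros(n), s=np.linspace(0, 500, n), n=n)
        assert lat_dto(tr, 250.0) == 0.0

    def test_negative_side_absolute(self):
        n = 1000
        tr = make_trace(y=np.full(n, -0.5), s=np.linspace(0, 500, n), n=n)
        assert lat_dto(tr, 250.0) == pytest.approx(0.5)


class TestCollisions:
    def _trace_at(self, y_val):
        n = 2000
        s = np.linspace(0, 1000, n)
        return make_trace(y=np.full(n, y_val), s=s, n=n)

    def test_below_threshold_collides(self):
        count, flags = detect_collisions(self._trace_at(1.5), [500.0])
        assert count == 1 and flags == [True]

    def test_above_threshold_clear(self):
        count, _ = detect_collisions(self._trace_at(1.7), [500.0])
        assert count == 0

    def test_exactly_at_threshold_clear(self):
        count, _ = detect_collisions(self._trace_at(1.6), [500.0])
        assert count == 0

    def test_matches_brute_force_scan(self):
        # oracle: per-sample scan with explicit longitudinal-overlap test
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = 600
            s = np.sort(rng.uniform(0, 400, n))
            s[0], s[-1] = 0.0, 400.0
            y = rng.uniform(-1, 4, n)
            t = np.arange(n) / FS
            tr = SessionTrace("S3", t, s, y, np.zeros(n))
            obstacles = rng.uniform(50, 350, 3)
            lengths = [4.5, 1.8, 4.5]
            _, flags = detect_collisions(tr, obstacles,
                                         obstacle_lengths_m=lengths)
            for pos, olen, flag in zip(obstacles, lengths, flags):
                hit = False
                for si, yi in zip(s, y):
                    if abs(si - pos) <= (4.5 + olen) / 2 and abs(yi) < 1.6:
                        hit = True
                assert flag == hit


class TestSessionMetrics:
    COURSE = CourseSpec()

    def _simulated_trace(self, session):
        from glaucodrive.cohort_sim import ParticipantProfile, simulate_drive
        p = ParticipantProfile(id="T", group="control")
        return simulate_drive(p, self.COURSE, session, 77)

    def test_s1_reports_obstacle_window_sa(self):
        # obstacle-period SA is computed from the windows regardless of
        # whether obstacles were present in the session
        m = session_driving_metrics(self._simulated_trace("S1"), self.COURSE)
        assert m.sa_high_obstacle > 0
        assert m.long_dto_m == [] and m.collisions == 0

    def test_s3_has_nine_defined_avoidances(self):
        m = session_driving_metrics(self._simulated_trace("S3"), self.COURSE)
        assert len(m.long_dto_m) == 9
        assert m.n_undefined_long_dto == 0
        assert len(m.lat_dto_m) == 9
        assert all(v >= 1.6 for v in m.lat_dto_m)
        assert m.collisions == 0

    def test_noise_free_centred_trace_near_zero(self):
        from glaucodrive.cohort_sim import ParticipantProfile, simulate_drive
        p = ParticipantProfile(id="T", group="control",
                               steering_noise_gain=0.0, fast_noise_gain=0.0,
                               lane_wander_rms_m=0.0)
        tr = simulate_drive(p, self.COURSE, "S1", 3)
        m = session_driving_metrics(tr, self.COURSE)
        assert m.sdlp_nonobstacle == pytest.approx(0.0, abs=1e-6)
        assert m.sa_high_nonobstacle == pytest.approx(0.0, abs=1e-6)
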