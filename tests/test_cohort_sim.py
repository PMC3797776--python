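"""Synthetic-cohort generator tests: determinism, construction, effects."""

import numpy as np
import pytest

from glaucodrive.cohort_sim import (
    DEFAULT_PATTERN_COUNTS, EffectConfig, ParticipantProfile,
    generate_cohort, generate_visual_fields, simulate_drive, simulate_gaze,
    simulate_letter_responses,
)
from glaucodrive.course import (CourseSpec, LetterScheduleSpec,
                                generate_letter_schedule)
from glaucodrive.driving_metrics import session_driving_metrics
from glaucodrive.gaze_metrics import preprocess
from glaucodrive.letter_scoring import score_letters
from glaucodrive.pipeline import cohort_measures
from glaucodrive.visual_field import integrate, quadrant_loss

COURSE = CourseSpec()


def control_profile(**kw) -> ParticipantProfile:
    return ParticipantProfile(id="C", group="control", **kw)


def patient_profile(pattern="both_upper", depth=25.0, **kw) -> ParticipantProfile:
    return ParticipantProfile(id="G", group="glaucoma",
                              scotoma_pattern=pattern,
                              scotoma_depth_db=depth, **kw)


class TestVisualFieldGeneration:
    def test_both_upper_depresses_upper_hemifield(self):
        od, os_ = generate_visual_fields(patient_profile(), 3)
        for vf in (od, os_):
            f = vf.to_frame()
            f = f[~f.blind_spot]
            upper = f[f.y_deg > 0].sensitivity_db.mean()
            lower = f[f.y_deg < 0].sensitivity_db.mean()
            assert upper < 10.0          # deep scotoma region
            assert lower > 20.0          # spared except background loss

    def test_control_fields_nearly_intact(self):
        losses = []
        for seed in range(10):
            od, os_ = generate_visual_fields(control_profile(), seed)
            ivf = integrate(od, os_)
            losses.append(np.mean(ivf.sensitivity_db < 25.0))
        assert np.mean(losses) < 0.05

    def test_same_seed_identical(self):
        a = generate_visual_fields(patient_profile(), 9)
        b = generate_visual_fields(patient_profile(), 9)
        assert np.array_equal(a[0].sensitivity_db, b[0].sensitivity_db)
        assert np.array_equal(a[1].sensitivity_db, b[1].sensitivity_db)

    def test_alternated_pattern_compensated_in_ivf(self):
        # upper loss in one eye, lower in the fellow: the IVF keeps the
        # better value, so pattern damage largely cancels
        prof = patient_profile("alternated")
        prof.scotoma_depth_db = 25.0
        od, os_ = generate_visual_fields(prof, 4)
        mono_loss = max(
            max(quadrant_loss(od).values()), max(quadrant_loss(os_).values()))
        ivf_loss = max(quadrant_loss(integrate(od, os_)).values())
        assert mono_loss > 50.0
        assert ivf_loss < mono_loss


class TestSimulateDrive:
    def test_noise_free_straight_run_is_quiet(self):
        p = control_profile(steering_noise_gain=0.0, fast_noise_gain=0.0,
                            lane_wander_rms_m=0.0)
        tr = simulate_drive(p, COURSE, "S1", 1)
        assert np.max(np.abs(tr.steer_deg)) < 1e-6
        assert np.max(np.abs(tr.y_m)) < 1e-6

    def test_s3_crosses_road_centre_before_each_obstacle(self):
        tr = simulate_drive(control_profile(), COURSE, "S3", 2)
        for pos in COURSE.obstacle_positions_m:
            before = (tr.s_m > pos - 150) & (tr.s_m <= pos)
            assert np.max(tr.y_m[before]) > 1.8

    def test_avoidance_clearance_at_least_collision_margin(self):
        for seed in range(3):
            tr = simulate_drive(control_profile(), COURSE, "S3", 30 + seed)
            m = session_driving_metrics(tr, COURSE, "S3")
            assert all(v >= 1.6 for v in m.lat_dto_m)
            assert m.collisions == 0

    def test_no_lane_change_in_non_obstacle_sessions(self):
        tr = simulate_drive(control_profile(), COURSE, "S2", 3)
        assert np.max(tr.y_m) < 1.8

    def test_within_road_edges(self):
        for seed in range(3):
            tr = simulate_drive(patient_profile(), COURSE, "S4", seed)
            assert tr.y_m.min() >= -1.8 and tr.y_m.max() <= 5.4

    def test_sa_low_monotone_in_noise_gain(self):
        # Monte-Carlo: mean SA-low increases with the noise gain
        means = []
        for gain in (0.7, 1.4, 2.8):
            vals = []
            for seed in range(50):
                p = control_profile(steering_noise_gain=gain)
                tr = simulate_drive(p, COURSE, "S1", 1000 + seed)
                m = session_driving_metrics(tr, COURSE, "S1")
                vals.append(m.sa_low_nonobstacle)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_unknown_session_rejected(self):
        with pytest.raises(ValueError):
            simulate_drive(control_profile(), COURSE, "S5", 1)


class TestSimulateLetters:
    def _ivf(self, value):
        from glaucodrive.visual_field import VisualField, build_grid_24_2
        grid = build_grid_24_2("OD")
        od = VisualField("OD", grid, np.full(54, value), md_db=0.0)
        grid_os = build_grid_24_2("OS")
        os_ = VisualField("OS", grid_os, np.full(54, value), md_db=0.0)
        return integrate(od, os_)

    def test_healthy_field_mostly_detected(self):
        # sensitivity 30 dB vs threshold 15: detection p > 0.95
        sched = generate_letter_schedule(LetterScheduleSpec(), 5)
        prof = control_profile(detection_threshold_db=15.0,
                               periphery_floor_db=30.0)
        n_det = []
        for seed in range(20):
            log = simulate_letter_responses(prof, self._ivf(30.0), sched, seed)
            n_det.append(len(log.voice_events))
        assert np.mean(n_det) > 0.95 * 32

    def test_deep_scotoma_mostly_missed(self):
        # letters land on a 0 dB field: miss probability > 0.9
        sched = generate_letter_schedule(LetterScheduleSpec(), 5)
        prof = control_profile(detection_threshold_db=15.0,
                               periphery_floor_db=0.0)
        n_det = []
        for seed in range(20):
            log = simulate_letter_responses(prof, self._ivf(0.0), sched, seed)
            n_det.append(len(log.voice_events))
        assert np.mean(n_det) < 0.1 * 32

    def test_voice_events_scoreable(self):
        sched = generate_letter_schedule(LetterScheduleSpec(), 6)
        prof = control_profile()
        log = simulate_letter_responses(prof, self._ivf(30.0), sched, 7)
        score = score_letters(log.letters, log.voice_events)
        assert score.spurious_voice_events == []
        assert score.n_detected == len(log.voice_events)


class TestSimulateGaze:
    def test_zero_jitter_no_letters_stays_at_anchor(self):
        p = control_profile(gaze_jitter_mm=0.0, blink_rate_hz=0.0,
                            dropout_rate_hz=0.0, aoi_visit_rate_hz=0.0)
        g = simulate_gaze(p, None, 4)
        anchor = p.eye_point_mm[:2]
        dist = np.hypot(g.x_mm - anchor[0], g.y_mm - anchor[1])
        three_deg_mm = np.radians(3.0) * p.eye_point_mm[2]
        assert np.all(dist <= three_deg_mm)

    def test_blink_gap_count_near_poisson_mean(self):
        p = control_profile(blink_rate_hz=0.2, dropout_rate_hz=0.0,
                            aoi_visit_rate_hz=0.0)
        counts = []
        for seed in range(15):
            g = simulate_gaze(p, None, 200 + seed)
            inval = ~g.valid
            starts = np.flatnonzero(np.diff(inval.astype(int)) == 1) + 1
            n = len(starts) + int(inval[0])
            counts.append(n)
        # Poisson mean 0.2 * 278 = 55.6 (slightly fewer after overlaps)
        assert 45 <= np.mean(counts) <= 60

    def test_default_profile_low_band_dwell(self):
        from glaucodrive.gaze_metrics import region_dwell
        p = control_profile()
        dwell_tot = []
        for seed in range(5):
            clean = preprocess(simulate_gaze(p, None, 300 + seed))
            d = region_dwell(clean)
            dwell_tot.append(d["top"] + d["bottom"])
        assert np.mean(dwell_tot) < 5.0


class TestGenerateCohort:
    def test_default_composition(self):
        recs = generate_cohort(rng_seed=0, components=("fields",))
        groups = [r.profile.group for r in recs]
        assert groups.count("control") == 12
        assert groups.count("glaucoma") == 23
        patterns = [r.profile.scotoma_pattern for r in recs
                    if r.profile.group == "glaucoma"]
        for pattern, count in DEFAULT_PATTERN_COUNTS.items():
            assert patterns.count(pattern) == count

    def test_control_only_cohort(self):
        recs = generate_cohort(n_control=4, n_glaucoma=0, pattern_counts={},
                               components=("fields",), rng_seed=1)
        assert all(r.profile.scotoma_pattern == "none" for r in recs)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(n_glaucoma=5, pattern_counts={"both_upper": 3},
                            rng_seed=0)

    def test_fixed_seed_reproducible(self):
        a = generate_cohort(n_control=2, n_glaucoma=2,
                            pattern_counts={"both_upper": 2},
                            components=("fields", "letters", "tlx"),
                            rng_seed=5)
        b = generate_cohort(n_control=2, n_glaucoma=2,
                            pattern_counts={"both_upper": 2},
                            components=("fields", "letters", "tlx"),
                            rng_seed=5)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.vf_od.sensitivity_db,
                                  rb.vf_od.sensitivity_db)
            assert ra.events["S2"].voice_events == rb.events["S2"].voice_events
            assert all(np.array_equal(ra.tlx[s], rb.tlx[s]) for s in ra.tlx)

    def test_skipping_components_leaves_others_unchanged(self):
        full = generate_cohort(n_control=1, n_glaucoma=1,
                               pattern_counts={"both_upper": 1},
                               components=("fields", "letters"), rng_seed=6)
        partial = generate_cohort(n_control=1, n_glaucoma=1,
                                  pattern_counts={"both_upper": 1},
                                  components=("fields",), rng_seed=6)
        for rf, rp in zip(full, partial):
            assert np.array_equal(rf.vf_od.sensitivity_db,
                                  rp.vf_od.sensitivity_db)


N_NULL_REPLICATES = 20


@pytest.fixture(scope="module")
def replicate_diffs():
    rows = []
    for seed in range(N_NULL_REPLICATES):
        recs = generate_cohort(rng_seed=10_000 + seed,
                               components=("fields", "traces", "gaze"))
        m = cohort_measures(recs)
        eye = m[~m.eye_excluded.astype(bool)] if "eye_excluded" in m else m
        gm = m.groupby("group").mean(numeric_only=True)
        ge = eye.groupby("group").mean(numeric_only=True)
        rows.append({
            "sdlp": gm.loc["glaucoma", "sdlp_nonobstacle"]
                    - gm.loc["control", "sdlp_nonobstacle"],
            "lat_dto": gm.loc["glaucoma", "lat_dto_mean"]
                       - gm.loc["control", "lat_dto_mean"],
            "fix_rate": ge.loc["glaucoma", "fixations_per_s"]
                        - ge.loc["control", "fixations_per_s"],
            "sa_low": gm.loc["glaucoma", "sa_low_nonobstacle"]
                      - gm.loc["control", "sa_low_nonobstacle"],
        })
    import pandas as pd
    return pd.DataFrame(rows)


class TestReplicateNullStructure:
    """Measures the study reports as null must not separate the groups."""

    def test_sdlp_difference_centred_near_zero(self, replicate_diffs):
        assert abs(replicate_diffs.sdlp.mean()) < 0.04

    def test_lat_dto_difference_centred_near_zero(self, replicate_diffs):
        assert abs(replicate_diffs.lat_dto.mean()) < 0.15

    def test_fixation_rate_difference_centred_near_zero(self, replicate_diffs):
        assert abs(replicate_diffs.fix_rate.mean()) < 0.08

    def test_sa_low_difference_positive(self, replicate_diffs):
        assert (replicate_diffs.sa_low > 0).mean() >= 0.9
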