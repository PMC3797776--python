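"""Synthetic cohort generator for the driving-simulator study design.

Produces complete participant records — per-eye 24-2 visual fields, four
278 s driving sessions, letter-task event logs, 60 Hz gaze streams and
NASA-TLX ratings — for a cohort of glaucoma patients and controls, with
configurable group effect sizes.  The generator emulates the statistical
structure the analysis pipeline assumes:

* patients carry one of five scotoma patterns (one eye only, alternated
  upper/lower between eyes, or the same hemifield of both eyes), with
  sensitivities depressed by a configurable depth;
* steering is a proportional-derivative lane tracker plus band-limited
  steering noise, with patients applying more (and faster) steering
  noise and slightly tighter tracking, so steering activity separates
  the groups while lane keeping (SDLP) does not;
* letter detection is a logistic function of the integrated-field
  sensitivity in the letter's direction with gaze fixed at the focus of
  expansion, so upper-field loss drives letter misses;
* reaction times grow with eccentricity and with overall field loss;
* gaze concentrates near the focus of expansion with brief excursions
  to detected letters, blink gaps, and tracking-dropout segments.

All randomness flows from a single seed through ``numpy``'s
``SeedSequence`` spawning: the cohort seed spawns one sequence per
participant, which spawns one child per data component (fields, each
session's trace, events, gaze, TLX), so any component can be generated
or skipped independently without perturbing the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .course import (
    CourseSpec, LetterScheduleSpec, LetterEvent, DEFAULT_EYE_POINT_MM,
    default_accel_profile, generate_letter_schedule, position_at_time,
    eccentricity_deg,
)
from .driving_metrics import SessionTrace, SAMPLE_RATE_HZ
from .gaze_metrics import GazeStream, SCREEN_W_MM, SCREEN_H_MM
from .visual_field import VisualField, IntegratedField, build_grid_24_2, integrate

__all__ = [
    "ParticipantProfile",
    "ParticipantRecord",
    "EventLog",
    "EffectConfig",
    "DEFAULT_PATTERN_COUNTS",
    "generate_visual_fields",
    "simulate_drive",
    "simulate_letter_responses",
    "simulate_gaze",
    "generate_cohort",
]

SCOTOMA_PATTERNS = ("none", "left_eye_only", "right_eye_only",
                    "alternated", "both_upper", "both_lower")

#: Scotoma-pattern composition of the recruited glaucoma group.
RECRUITED_PATTERN_COUNTS = {
    "left_eye_only": 4,
    "right_eye_only": 7,
    "alternated": 5,
    "both_upper": 6,
    "both_lower": 3,
}

#: Default composition of the 23 analysed patients.  Two of the 25
#: recruited patients withdrew before testing; which patterns they had
#: is not recorded, so one patient is trimmed from each of the two
#: largest pattern groups.
DEFAULT_PATTERN_COUNTS = {
    "left_eye_only": 4,
    "right_eye_only": 6,
    "alternated": 5,
    "both_upper": 5,
    "both_lower": 3,
}

SESSIONS = ("S1", "S2", "S3", "S4")
LETTER_SESSIONS = ("S2", "S4")
OBSTACLE_SESSIONS = ("S3", "S4")

# vehicle/steering geometry for the kinematic lateral model
_WHEELBASE_M = 2.7
_STEERING_RATIO = 18.0
_FOE_ANCHOR_MM = DEFAULT_EYE_POINT_MM[:2]  # focus of expansion on screen


@dataclass
class ParticipantProfile:
    """Latent per-participant parameters driving all simulated behaviour."""

    id: str
    group: str                      # control | glaucoma
    scotoma_pattern: str = "none"
    scotoma_depth_db: float = 0.0
    steering_noise_gain: float = 1.4    # deg RMS of slow steering noise
    fast_noise_gain: float = 0.30       # deg RMS of fast (0.5-1.5 Hz) noise
    tracking_gain_scale: float = 1.0    # multiplies the PD gains
    avoidance_initiation_m: float = 78.0  # road-centre commit point, m before obstacle
    lane_change_ramp_m: float = 70.0     # length of the steer-over ramp
    lane_change_plateau_m: float = 3.2    # lateral offset held while passing
    lane_return_after_m: float = 40.0     # plateau held this far past the obstacle
    lane_wander_rms_m: float = 0.40       # slow attentional wander of held position
    detection_threshold_db: float = 15.0
    detection_slope_per_db: float = 0.4
    periphery_floor_db: float = 20.0    # sensitivity beyond the IVF margin
    rt_base_s: float = 0.78
    rt_ecc_slope_s_per_deg: float = 0.010
    blink_rate_hz: float = 0.15
    dropout_rate_hz: float = 0.008
    dropout_median_s: float = 1.5
    gaze_jitter_mm: float = 8.0
    gaze_jitter_tau_s: float = 1.5
    aoi_visit_rate_hz: float = 0.22     # glances to mirrors/speedometer/road
    tlx_base_pct: float = 25.0
    tlx_trend_pct_per_session: float = 0.0
    age_years: float = 65.0
    eye_point_mm: tuple[float, float, float] = DEFAULT_EYE_POINT_MM

    def __post_init__(self) -> None:
        if self.group not in ("control", "glaucoma"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.scotoma_pattern not in SCOTOMA_PATTERNS:
            raise ValueError(f"unknown scotoma pattern {self.scotoma_pattern!r}")
        if self.group == "control" and self.scotoma_pattern != "none":
            raise ValueError("controls must have scotoma pattern 'none'")
        for name in ("scotoma_depth_db", "steering_noise_gain", "fast_noise_gain",
                     "blink_rate_hz", "dropout_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class EventLog:
    """Letter onsets/positions and voice-response timestamps for a session."""

    letters: list[LetterEvent]
    voice_events: list[float]


@dataclass
class ParticipantRecord:
    profile: ParticipantProfile
    vf_od: VisualField | None = None
    vf_os: VisualField | None = None
    ivf: IntegratedField | None = None
    traces: dict[str, SessionTrace] = field(default_factory=dict)
    events: dict[str, EventLog] = field(default_factory=dict)
    gaze: dict[str, GazeStream] = field(default_factory=dict)
    tlx: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class EffectConfig:
    """Group-level effect sizes and between-subject spreads.

    Defaults are set so that a default cohort lands near the study's
    control-group descriptive level for steering activity, SDLP, letter
    misses and reaction times, with patient/control contrasts in the
    directions the study reports (more steering activity, more misses,
    longer reaction times; no lane-keeping or avoidance difference).
    """

    # steering
    control_noise_gain: float = 1.4
    patient_noise_ratio: float = 1.35
    fast_noise_control: float = 0.30
    patient_fast_noise_ratio: float = 1.6
    patient_tracking_gain_scale: float = 1.2
    noise_gain_cv: float = 0.18          # between-subject lognormal CV
    # visual fields
    scotoma_depth_mean_db: float = 25.0
    scotoma_depth_sd_db: float = 4.0
    # letter task
    detection_threshold_db: float = 13.0
    rt_base_mean_s: float = 0.78
    rt_base_sd_s: float = 0.10
    rt_loss_coef_s: float = 0.95         # s per unit IVF loss fraction
    # gaze quality: probability of a poor-tracking participant whose
    # dropout drives the removed fraction past the exclusion limit
    p_poor_tracking_control: float = 1.0 / 12.0
    p_poor_tracking_patient: float = 7.0 / 23.0
    poor_dropout_rate_hz: float = 0.06
    poor_dropout_median_s: float = 15.0
    # obstacle handling: patients steer over more abruptly
    control_ramp_m: float = 70.0
    patient_ramp_m: float = 52.0
    ramp_sd_m: float = 8.0
    # workload
    tlx_control_base: float = 26.5
    tlx_control_trend: float = -1.0
    tlx_patient_base: float = 18.0
    tlx_patient_trend: float = 4.0
    tlx_between_sd: float = 13.0


# ---------------------------------------------------------------------------
# Visual fields
# ---------------------------------------------------------------------------

_BASELINE_DB = 31.0
_ECC_DECLINE_DB_PER_DEG = 0.08
_POINT_NOISE_SD_DB = 1.2


def _healthy_template(grid) -> np.ndarray:
    ecc = np.hypot(grid.x_deg.to_numpy(), grid.y_deg.to_numpy())
    return _BASELINE_DB - _ECC_DECLINE_DB_PER_DEG * ecc


def _hemifields_for(pattern: str, rng: np.random.Generator) -> dict[str, str]:
    """Affected hemifield per eye ('upper'/'lower'/'all'/'') for a pattern."""
    coin = rng.random() < 0.5
    if pattern == "none":
        return {"OD": "", "OS": ""}
    if pattern == "left_eye_only":
        return {"OD": "", "OS": "upper" if coin else "lower"}
    if pattern == "right_eye_only":
        return {"OD": "upper" if coin else "lower", "OS": ""}
    if pattern == "alternated":
        return ({"OD": "upper", "OS": "lower"} if coin
                else {"OD": "lower", "OS": "upper"})
    if pattern == "both_upper":
        return {"OD": "upper", "OS": "upper"}
    if pattern == "both_lower":
        return {"OD": "lower", "OS": "lower"}
    raise ValueError(pattern)


def generate_visual_fields(profile: ParticipantProfile,
                           rng_seed: int | np.random.Generator
                           ) -> tuple[VisualField, VisualField]:
    """Simulate one participant's (OD, OS) 24-2 fields.

    Healthy sensitivity declines mildly with eccentricity from ~31 dB
    plus measurement noise.  Patients get two superimposed kinds of
    damage:

    * the recruitment scotoma pattern — a deep depression (the
      profile's scotoma depth, with per-point variability) over the
      affected hemifield(s)/eye(s);
    * bilateral background loss — glaucomatous damage is rarely
      confined to one region, so a random subset of visual-space
      locations, shared between the eyes and drawn independently per
      hemifield (severity fraction uniform on [0, 0.55] per
      hemifield), is depressed in both eyes.  Sharing the locations
      between eyes makes the loss binocular, hence visible in the
      integrated field, as in the study's patients (mean IVF loss
      ~40 % despite the pattern-based recruitment).

    Sensitivities are floored at 0 dB; blind-spot points sit near
    0 dB.  The mean deviation is the mean departure from the healthy
    template over non-blind-spot points.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    hemis = _hemifields_for(profile.scotoma_pattern, rng)
    is_patient = profile.scotoma_pattern != "none"
    # bilateral background loss: same visual-space locations in both
    # eyes, independent severities for the upper and lower hemifield
    ref_grid = build_grid_24_2("OD")
    ref_y = ref_grid.y_deg.to_numpy()
    ref_key = {(x, y): i for i, (x, y) in enumerate(
        zip(ref_grid.x_deg, ref_grid.y_deg))}
    background = np.zeros(len(ref_grid))
    if is_patient and profile.scotoma_depth_db > 0:
        for hemi_mask in (ref_y > 0, ref_y < 0):
            severity = rng.uniform(0.0, 0.55)
            hit = rng.random(len(ref_grid)) < severity
            depth = profile.scotoma_depth_db * rng.uniform(0.35, 0.85,
                                                           len(ref_grid))
            background[hemi_mask & hit] = depth[hemi_mask & hit]
    fields = {}
    for eye in ("OD", "OS"):
        grid = build_grid_24_2(eye)
        sens = _healthy_template(grid) + rng.normal(0, _POINT_NOISE_SD_DB,
                                                    len(grid))
        # map this eye's locations into the OD visual-space frame
        bg_idx = [ref_key.get((x, y), None)
                  for x, y in zip(grid.x_deg, grid.y_deg)]
        bg = np.array([background[i] if i is not None else 0.0
                       for i in bg_idx])
        sens -= bg
        hemi = hemis[eye]
        if hemi and profile.scotoma_depth_db > 0:
            y = grid.y_deg.to_numpy()
            affected = y > 0 if hemi == "upper" else y < 0
            depth = profile.scotoma_depth_db * rng.uniform(0.8, 1.0,
                                                           affected.sum())
            sens[affected] = np.minimum(sens[affected],
                                        _healthy_template(grid)[affected]
                                        - depth)
        blind = grid.blind_spot.to_numpy()
        sens[blind] = rng.uniform(0.0, 2.0, blind.sum())
        sens = np.clip(sens, 0.0, None)
        md = float(np.mean((sens - _healthy_template(grid))[~blind]))
        fields[eye] = VisualField(eye, grid, sens, md_db=md)
    return fields["OD"], fields["OS"]


# ---------------------------------------------------------------------------
# Driving
# ---------------------------------------------------------------------------

def _filtered_noise(rng: np.random.Generator, n: int, rms: float,
                    cutoff_hz: float, highpass_hz: float | None = None
                    ) -> np.ndarray:
    """Band-limited Gaussian noise with the requested RMS."""
    if rms <= 0:
        return np.zeros(n)
    w = rng.standard_normal(n + 600)
    b, a = signal.butter(2, cutoff_hz, fs=SAMPLE_RATE_HZ)
    x = signal.lfilter(b, a, w)
    if highpass_hz:
        bh, ah = signal.butter(2, highpass_hz, btype="high", fs=SAMPLE_RATE_HZ)
        x = signal.lfilter(bh, ah, x)
    x = x[600:]
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _target_lane(profile: ParticipantProfile, course: CourseSpec,
                 s_m: np.ndarray, with_obstacles: bool) -> np.ndarray:
    """Target lateral position along the course (right-lane centre = 0).

    Around each obstacle the target ramps over to a plateau left of the
    obstacle and back: the ramp is centred so the target crosses the
    road centre about ``avoidance_initiation_m`` before the obstacle,
    and its length sets how gently the driver steers over.
    """
    if not with_obstacles:
        return np.zeros_like(s_m)
    r2 = profile.lane_change_ramp_m / 2.0
    plateau = profile.lane_change_plateau_m
    xs: list[float] = [0.0]
    ys: list[float] = [0.0]
    for pos in course.obstacle_positions_m:
        start = pos - profile.avoidance_initiation_m
        xs += [start - r2, start + r2,
               pos + profile.lane_return_after_m,
               pos + profile.lane_return_after_m + profile.lane_change_ramp_m]
        ys += [0.0, plateau, plateau, 0.0]
    target = np.interp(s_m, xs, ys)
    # round the trapezoid corners (zero phase)
    b, a = signal.butter(2, 0.35, fs=SAMPLE_RATE_HZ)
    return signal.filtfilt(b, a, target)


def simulate_drive(profile: ParticipantProfile, course: CourseSpec,
                   session_id: str,
                   rng_seed: int | np.random.Generator) -> SessionTrace:
    """Simulate one session's vehicle trace.

    Lateral dynamics are kinematic (heading rate proportional to the
    steering-wheel angle, lateral speed = v·heading for the small
    headings involved); the steering command is a proportional-
    derivative tracker of the target lane centre — switching to the
    left lane ``avoidance_initiation_m`` before each obstacle in the
    obstacle sessions — plus band-limited steering noise and a slow
    lane-position wander shared by all drivers.  The linear closed loop
    is integrated with a zero-order-hold discretisation at 60 Hz.
    """
    if session_id not in SESSIONS:
        raise ValueError(f"unknown session {session_id!r}")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    n = int(round(course.session_duration_s * SAMPLE_RATE_HZ))
    dt = 1.0 / SAMPLE_RATE_HZ
    t = np.arange(n) * dt
    # longitudinal position: the default acceleration polynomial is
    # vectorised directly; cruise phase is linear (matches position_at_time)
    accel = default_accel_profile(
        np.minimum(t, course.cruise_reached_s),
        cruise_reached_s=course.cruise_reached_s,
        cruise_speed_mps=course.cruise_speed_mps)
    s_m = np.where(
        t < course.cruise_reached_s, accel,
        accel + (t - course.cruise_reached_s) * course.cruise_speed_mps)

    v = course.cruise_speed_mps
    c = (v / _WHEELBASE_M) / _STEERING_RATIO * np.pi / 180.0  # rad/s per deg
    omega, zeta = 2.2, 0.85  # closed-loop natural freq (rad/s) and damping
    kp = omega ** 2 / (c * v) * profile.tracking_gain_scale
    kd = 2 * zeta * omega / (c * v) * profile.tracking_gain_scale

    with_obstacles = session_id in OBSTACLE_SESSIONS
    target = _target_lane(profile, course, s_m, with_obstacles)
    # slow attentional wander of the held lane position (shared dynamics,
    # independent realisation per session)
    target = target + _filtered_noise(rng, n, rms=profile.lane_wander_rms_m,
                                      cutoff_hz=0.04)
    noise = (_filtered_noise(rng, n, profile.steering_noise_gain,
                             cutoff_hz=0.3)
             + _filtered_noise(rng, n, profile.fast_noise_gain,
                               cutoff_hz=1.5, highpass_hz=0.5))

    # states [y, heading]; inputs [target, noise]; zero-order-hold
    # discretisation, run through per-input transfer functions so the
    # recursion happens in lfilter
    A = np.array([[0.0, v], [-c * kp, -c * kd * v]])
    B = np.array([[0.0, 0.0], [c * kp, c]])
    Ad, Bd, *_ = signal.cont2discrete((A, B, np.eye(2), np.zeros((2, 2))),
                                      dt=dt, method="zoh")
    u = np.column_stack([target, noise])
    ys = np.zeros(n)
    hs = np.zeros(n)
    for j in range(2):
        num, den = signal.ss2tf(Ad, Bd[:, [j]], np.eye(2), np.zeros((2, 1)))
        # D = 0, so the transfer functions are strictly proper and lfilter
        # reproduces x[k+1] = Ad x[k] + Bd u[k] exactly
        ys += signal.lfilter(num[0], den, u[:, j])
        hs += signal.lfilter(num[1], den, u[:, j])
    steer = kp * (target - ys) - kd * v * hs + noise
    # road-edge saturation (right edge at -1.8 m, left edge at +5.4 m)
    ys = np.clip(ys, -course.lane_width_m / 2 + 0.05,
                 1.5 * course.lane_width_m - 0.05)
    return SessionTrace(session_id=session_id, t=t, s_m=s_m, y_m=ys,
                        steer_deg=steer)


# ---------------------------------------------------------------------------
# Letter task
# ---------------------------------------------------------------------------

IVF_MARGIN_DEG = 21.0
RESPONSE_WINDOW_S = 5.0


def _letter_field_position(x_mm: float, y_mm: float,
                           eye_point_mm: tuple[float, float, float],
                           gaze_anchor_mm: tuple[float, float]
                           ) -> tuple[float, float]:
    """Visual-field direction (deg, x right / y up) of a screen point
    for gaze fixed at the anchor."""
    ex, ey, d = eye_point_mm
    ax = np.degrees(np.arctan((x_mm - ex) / d))
    ay = np.degrees(np.arctan((y_mm - ey) / d))
    gx = np.degrees(np.arctan((gaze_anchor_mm[0] - ex) / d))
    gy = np.degrees(np.arctan((gaze_anchor_mm[1] - ey) / d))
    return float(ax - gx), float(ay - gy)


def ivf_sensitivity_at(ivf: IntegratedField, x_deg: float, y_deg: float,
                       margin_deg: float = IVF_MARGIN_DEG,
                       floor_db: float = 20.0) -> float:
    """Nearest-location IVF sensitivity; the floor applies beyond the margin."""
    if np.hypot(x_deg, y_deg) > margin_deg + 3.0:
        return floor_db
    lx = ivf.locations.x_deg.to_numpy()
    ly = ivf.locations.y_deg.to_numpy()
    i = int(np.argmin(np.hypot(lx - x_deg, ly - y_deg)))
    return float(ivf.sensitivity_db[i])


def simulate_letter_responses(profile: ParticipantProfile,
                              ivf: IntegratedField,
                              schedule: Sequence[LetterEvent],
                              rng_seed: int | np.random.Generator,
                              gaze_anchor_mm: tuple[float, float] = _FOE_ANCHOR_MM,
                              ) -> EventLog:
    """Detection and voice-response simulation for one letter session.

    Each letter's visual-field direction is evaluated with gaze at the
    focus of expansion; the miss probability is logistic in
    (detection threshold − IVF sensitivity).  Detected letters get a
    voice time onset + base RT + eccentricity slope · eccentricity +
    lognormal noise; responses that would fall outside the 5 s window
    (display + 1 s grace) become misses.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    d = profile.eye_point_mm[2]
    voices: list[float] = []
    for ev in schedule:
        fx, fy = _letter_field_position(ev.x_mm, ev.y_mm,
                                        profile.eye_point_mm, gaze_anchor_mm)
        sens = ivf_sensitivity_at(ivf, fx, fy,
                                  floor_db=profile.periphery_floor_db)
        p_miss = 1.0 / (1.0 + np.exp(
            -profile.detection_slope_per_db
            * (profile.detection_threshold_db - sens)))
        if rng.random() < p_miss:
            continue
        ecc = eccentricity_deg(ev.x_mm, ev.y_mm, gaze_anchor_mm, d)
        rt = (profile.rt_base_s
              + profile.rt_ecc_slope_s_per_deg * ecc
              + float(rng.lognormal(mean=np.log(0.10), sigma=0.5)))
        if rt > RESPONSE_WINDOW_S:
            continue
        voices.append(ev.onset_s + rt)
    return EventLog(letters=list(schedule), voice_events=sorted(voices))


# ---------------------------------------------------------------------------
# Gaze
# ---------------------------------------------------------------------------

def _ou_jitter(rng: np.random.Generator, n: int, sd_mm: float,
               tau_s: float = 0.3) -> np.ndarray:
    """Ornstein-Uhlenbeck positional jitter around zero (AR(1) recursion)."""
    if n == 0:
        return np.zeros(0)
    dt = 1.0 / SAMPLE_RATE_HZ
    a = np.exp(-dt / tau_s)
    innov = rng.standard_normal(n) * sd_mm * np.sqrt(1 - a * a)
    innov[0] = rng.normal(0, sd_mm)
    return signal.lfilter([1.0], [1.0, -a], innov)


#: Glance targets in the simulated scene, as (x_mm, y_mm, weight):
#: speedometer below the focus of expansion, rear-view mirror above,
#: right side mirror, and two road-scene points flanking the lane.
SCENE_AOIS_MM = (
    (150.0, 60.0, 0.06),    # speedometer (bottom band)
    (450.0, 690.0, 0.06),   # rear-view mirror (top band)
    (750.0, 350.0, 0.25),   # right side mirror
    (40.0, 330.0, 0.30),    # road scene, left of lane
    (390.0, 340.0, 0.33),   # road scene, right of lane
)


def simulate_gaze(profile: ParticipantProfile,
                  schedule: Sequence[LetterEvent] | None,
                  rng_seed: int | np.random.Generator,
                  duration_s: float = 278.0,
                  anchor_mm: tuple[float, float] = _FOE_ANCHOR_MM,
                  excursion_prob: float = 0.85,
                  ) -> GazeStream:
    """Simulate one session's 60 Hz gaze stream.

    Gaze dwells at the focus-of-expansion anchor with slow drift and
    small jitter, glances briefly at scene targets (mirrors,
    speedometer, road scene) at the profile's visit rate, makes
    excursions toward projected letters (saccade ~0.25 s after onset,
    ~0.5 s dwell, then return), and is interrupted by blink gaps
    (invalid runs at the profile's blink rate) and tracking-dropout
    segments.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    n = int(round(duration_s * SAMPLE_RATE_HZ))
    t = np.arange(n) / SAMPLE_RATE_HZ
    x = anchor_mm[0] + _ou_jitter(rng, n, profile.gaze_jitter_mm,
                                  tau_s=profile.gaze_jitter_tau_s)
    y = anchor_mm[1] + _ou_jitter(rng, n, profile.gaze_jitter_mm * 0.8,
                                  tau_s=profile.gaze_jitter_tau_s)

    def visit(t0: float, dwell: float, px: float, py: float) -> None:
        i0 = int(t0 * SAMPLE_RATE_HZ)
        i1 = min(int((t0 + dwell) * SAMPLE_RATE_HZ), n)
        i0 = min(i0, n)
        if i1 > i0:
            x[i0:i1] = px + _ou_jitter(rng, i1 - i0, 5.0)
            y[i0:i1] = py + _ou_jitter(rng, i1 - i0, 5.0)

    aois = np.array([(a[0], a[1]) for a in SCENE_AOIS_MM])
    weights = np.array([a[2] for a in SCENE_AOIS_MM])
    weights = weights / weights.sum()
    n_visits = rng.poisson(profile.aoi_visit_rate_hz * duration_s)
    for t0 in np.sort(rng.uniform(0, duration_s, n_visits)):
        px, py = aois[rng.choice(len(aois), p=weights)]
        visit(t0, 0.35 + rng.uniform(0, 0.4), px, py)
    if schedule:
        for ev in schedule:
            if rng.random() > excursion_prob:
                continue
            visit(ev.onset_s + 0.25 + rng.uniform(0, 0.1),
                  0.45 + rng.uniform(0, 0.2), ev.x_mm, ev.y_mm)
    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(profile.blink_rate_hz * duration_s)
    for t0 in rng.uniform(0, duration_s, n_blinks):
        dur = max(2.0 / SAMPLE_RATE_HZ, rng.normal(0.15, 0.04))
        i0 = int(t0 * SAMPLE_RATE_HZ)
        valid[i0:i0 + int(dur * SAMPLE_RATE_HZ)] = False
    n_drop = rng.poisson(profile.dropout_rate_hz * duration_s)
    for t0 in rng.uniform(0, duration_s, n_drop):
        dur = rng.lognormal(np.log(profile.dropout_median_s), 0.5)
        i0 = int(t0 * SAMPLE_RATE_HZ)
        valid[i0:i0 + int(dur * SAMPLE_RATE_HZ)] = False
    x = np.clip(x, 0.0, SCREEN_W_MM)
    y = np.clip(y, 0.0, SCREEN_H_MM)
    x[~valid] = np.nan
    y[~valid] = np.nan
    return GazeStream(t=t, x_mm=x, y_mm=y, valid=valid)


# ---------------------------------------------------------------------------
# TLX and cohort assembly
# ---------------------------------------------------------------------------

def _simulate_tlx(profile: ParticipantProfile, session_index: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Six TLX item ratings (1-21) around the profile's session trend."""
    target_pct = (profile.tlx_base_pct
                  + profile.tlx_trend_pct_per_session * session_index)
    target_pct = float(np.clip(target_pct, 0.0, 100.0))
    items = 1.0 + 20.0 * target_pct / 100.0 + rng.normal(0, 1.5, 6)
    return np.clip(np.round(items), 1, 21)


def _draw_profile(pid: str, group: str, pattern: str, cfg: EffectConfig,
                  rng: np.random.Generator) -> ParticipantProfile:
    is_pat = group == "glaucoma"
    sigma = np.sqrt(np.log(1 + cfg.noise_gain_cv ** 2))
    gain = (cfg.control_noise_gain
            * (cfg.patient_noise_ratio if is_pat else 1.0)
            * rng.lognormal(-sigma * sigma / 2, sigma))
    fast = (cfg.fast_noise_control
            * (cfg.patient_fast_noise_ratio if is_pat else 1.0)
            * rng.lognormal(-sigma * sigma / 2, sigma))
    p_poor = (cfg.p_poor_tracking_patient if is_pat
              else cfg.p_poor_tracking_control)
    poor = rng.random() < p_poor
    return ParticipantProfile(
        id=pid,
        group=group,
        scotoma_pattern=pattern,
        scotoma_depth_db=(max(5.0, rng.normal(cfg.scotoma_depth_mean_db,
                                              cfg.scotoma_depth_sd_db))
                          if is_pat else 0.0),
        steering_noise_gain=gain,
        fast_noise_gain=fast,
        tracking_gain_scale=(cfg.patient_tracking_gain_scale if is_pat else 1.0),
        avoidance_initiation_m=rng.uniform(65.0, 92.0),
        lane_change_ramp_m=max(30.0, rng.normal(
            cfg.patient_ramp_m if is_pat else cfg.control_ramp_m,
            cfg.ramp_sd_m)),
        lane_change_plateau_m=rng.uniform(3.0, 3.5),
        lane_wander_rms_m=0.40 * rng.lognormal(0, 0.3),
        detection_threshold_db=cfg.detection_threshold_db,
        rt_base_s=rng.normal(cfg.rt_base_mean_s, cfg.rt_base_sd_s),
        blink_rate_hz=rng.uniform(0.10, 0.22),
        dropout_rate_hz=(cfg.poor_dropout_rate_hz if poor else 0.008),
        dropout_median_s=(cfg.poor_dropout_median_s if poor else 1.5),
        tlx_base_pct=float(np.clip(rng.normal(
            cfg.tlx_patient_base if is_pat else cfg.tlx_control_base,
            cfg.tlx_between_sd), 1.0, 90.0)),
        tlx_trend_pct_per_session=(cfg.tlx_patient_trend if is_pat
                                   else cfg.tlx_control_trend),
        age_years=rng.normal(65.0, 10.0),
    )


def generate_cohort(n_control: int = 12, n_glaucoma: int = 23,
                    pattern_counts: dict[str, int] | None = None,
                    effect_config: EffectConfig | None = None,
                    rng_seed: int = 0,
                    course: CourseSpec | None = None,
                    letter_spec: LetterScheduleSpec | None = None,
                    components: Sequence[str] = ("fields", "traces",
                                                 "letters", "gaze", "tlx"),
                    ) -> list[ParticipantRecord]:
    """Generate a full synthetic cohort.

    ``pattern_counts`` maps scotoma patterns to patient counts and must
    sum to ``n_glaucoma`` (default: the study's 4/7/5/6/3 composition
    for 23 patients).  ``components`` selects which data streams are
    synthesised; seed-splitting makes each component reproducible
    independently of the others.  One letter schedule is drawn per
    cohort and shared by all participants, with identical timing in S2
    and S4 (as in the study design).
    """
    cfg = effect_config or EffectConfig()
    course = course or CourseSpec()
    letter_spec = letter_spec or LetterScheduleSpec()
    if pattern_counts is None:
        pattern_counts = (dict(DEFAULT_PATTERN_COUNTS) if n_glaucoma == 23
                          else {"both_upper": n_glaucoma})
    if sum(pattern_counts.values()) != n_glaucoma:
        raise ValueError("pattern counts must sum to n_glaucoma")
    unknown = set(pattern_counts) - set(SCOTOMA_PATTERNS)
    if unknown:
        raise ValueError(f"unknown scotoma patterns: {sorted(unknown)}")

    root = np.random.SeedSequence(rng_seed)
    schedule_ss, profile_ss, *participant_ss = root.spawn(
        2 + n_control + n_glaucoma)
    schedule = generate_letter_schedule(
        letter_spec, np.random.default_rng(schedule_ss))
    profile_rng = np.random.default_rng(profile_ss)

    roster: list[tuple[str, str, str]] = []
    for i in range(n_control):
        roster.append((f"C{i + 1:02d}", "control", "none"))
    k = 0
    for pattern, count in pattern_counts.items():
        for _ in range(count):
            k += 1
            roster.append((f"G{k:02d}", "glaucoma", pattern))

    records: list[ParticipantRecord] = []
    for (pid, group, pattern), ss in zip(roster, participant_ss):
        profile = _draw_profile(pid, group, pattern, cfg, profile_rng)
        comp = {name: np.random.default_rng(child) for name, child in zip(
            ("fields", "trace_S1", "trace_S2", "trace_S3", "trace_S4",
             "events_S2", "events_S4", "gaze_S1", "gaze_S2", "gaze_S3",
             "gaze_S4", "tlx"),
            ss.spawn(12))}
        rec = ParticipantRecord(profile=profile)
        vf_od, vf_os = generate_visual_fields(profile, comp["fields"])
        rec.vf_od, rec.vf_os = vf_od, vf_os
        rec.ivf = integrate(vf_od, vf_os)
        # reaction time slows with overall integrated-field loss
        loss_frac = float(np.mean(rec.ivf.sensitivity_db < 25.0))
        profile.rt_base_s = max(0.3, profile.rt_base_s
                                + cfg.rt_loss_coef_s * loss_frac)
        if "traces" in components:
            for sid in SESSIONS:
                rec.traces[sid] = simulate_drive(profile, course, sid,
                                                 comp[f"trace_{sid}"])
        if "letters" in components:
            for sid in LETTER_SESSIONS:
                rec.events[sid] = simulate_letter_responses(
                    profile, rec.ivf, schedule, comp[f"events_{sid}"])
        if "gaze" in components:
            for sid in SESSIONS:
                rec.gaze[sid] = simulate_gaze(
                    profile, schedule if sid in LETTER_SESSIONS else None,
                    comp[f"gaze_{sid}"],
                    duration_s=course.session_duration_s)
        if "tlx" in components:
            for i, sid in enumerate(SESSIONS):
                rec.tlx[sid] = _simulate_tlx(profile, i, comp["tlx"])
        records.append(rec)
    return records
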