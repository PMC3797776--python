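"""Driving-performance measures from 60 Hz vehicle traces.

Steering activity (SA) is the mean absolute angular speed of the
steering wheel, computed on the steering signal lowpass filtered at
2 Hz (SA-high) or 0.5 Hz (SA-low); the low cutoff isolates slow
steering oscillations, the high one removes sensor noise while keeping
everything a human can physically steer.  SDLP is the standard
deviation of lateral position on non-obstacle road sections.  Obstacle
avoidance is summarised by the longitudinal distance to the obstacle at
the moment the vehicle commits to the left lane (LongDtO), the lateral
clearance when passing it (LatDtO), and a collision flag (lateral
clearance under 1.6 m while driving alongside the obstacle).

Sign conventions: lateral position y is metres left of the right-lane
centre; the road centre line sits at +1.8 m (half a lane width) and the
left-lane centre at +3.6 m.  Obstacles sit at y = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .course import CourseSpec, merge_intervals, obstacle_windows

__all__ = [
    "SessionTrace",
    "DrivingMetrics",
    "lowpass",
    "steering_activity",
    "sdlp",
    "long_dto",
    "lat_dto",
    "detect_collisions",
    "session_driving_metrics",
    "DEFAULT_OBSTACLE_LENGTHS_M",
]

SAMPLE_RATE_HZ = 60.0
ROAD_CENTER_Y_M = 1.8
COLLISION_LATERAL_M = 1.6
CAR_LENGTH_M = 4.5
EDGE_TRIM_S = 0.5

# three bicycles, three pairs of bicycles, three cars (course order:
# bicycle, pair, car, repeating); lengths in metres along the road
_BICYCLE_LEN = 1.8
DEFAULT_OBSTACLE_LENGTHS_M = (
    _BICYCLE_LEN, _BICYCLE_LEN, CAR_LENGTH_M,
    _BICYCLE_LEN, _BICYCLE_LEN, CAR_LENGTH_M,
    _BICYCLE_LEN, _BICYCLE_LEN, CAR_LENGTH_M,
)


@dataclass
class SessionTrace:
    """One 278 s session of 60 Hz vehicle kinematics."""

    session_id: str  # S1..S4
    t: np.ndarray           # seconds
    s_m: np.ndarray         # longitudinal position
    y_m: np.ndarray         # lateral position, +left of right-lane centre
    steer_deg: np.ndarray   # steering wheel angle, +left

    def __post_init__(self) -> None:
        for name in ("t", "s_m", "y_m", "steer_deg"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if any(len(getattr(self, k)) != n for k in ("s_m", "y_m", "steer_deg")):
            raise ValueError("trace columns must have equal length")
        dt = np.diff(self.t)
        if n > 1 and not np.allclose(dt, 1.0 / SAMPLE_RATE_HZ, atol=1e-6):
            raise ValueError("trace must be uniformly sampled at 60 Hz")
        if np.any(np.diff(self.s_m) < 0):
            raise ValueError("longitudinal position must be non-decreasing")


@dataclass
class DrivingMetrics:
    session_id: str
    sa_high_nonobstacle: float
    sa_high_obstacle: float
    sa_low_nonobstacle: float
    sa_low_obstacle: float
    sdlp_nonobstacle: float
    long_dto_m: list[float | None] = field(default_factory=list)
    lat_dto_m: list[float] = field(default_factory=list)
    collisions: int = 0
    collision_flags: list[bool] = field(default_factory=list)

    @property
    def long_dto_mean(self) -> float | None:
        vals = [v for v in self.long_dto_m if v is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def n_undefined_long_dto(self) -> int:
        return sum(v is None for v in self.long_dto_m)

    @property
    def lat_dto_mean(self) -> float | None:
        return float(np.mean(self.lat_dto_m)) if self.lat_dto_m else None


def lowpass(x: np.ndarray, cutoff_hz: float,
            fs_hz: float = SAMPLE_RATE_HZ) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth lowpass.

    Applied forward-backward (``filtfilt``), so there is no phase lag
    and the effective gain at the cutoff frequency is 0.5 (the single
    pass's −3 dB squared).
    """
    x = np.asarray(x, dtype=float)
    b, a = signal.butter(2, cutoff_hz, fs=fs_hz)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(x) <= 6 * padlen:
        raise ValueError(f"signal too short to filter ({len(x)} samples)")
    return signal.filtfilt(b, a, x)


def _edge_mask(n: int, fs_hz: float = SAMPLE_RATE_HZ,
               trim_s: float = EDGE_TRIM_S) -> np.ndarray:
    k = int(round(trim_s * fs_hz))
    m = np.ones(n, dtype=bool)
    m[:k] = False
    if k:
        m[-k:] = False
    return m


def steering_activity(steer_filtered_deg: np.ndarray, mask: np.ndarray,
                      fs_hz: float = SAMPLE_RATE_HZ) -> float:
    """Mean absolute steering-wheel speed (deg/s) over masked samples.

    The derivative is a central finite difference of the (already
    filtered) steering angle; samples within 0.5 s of the session
    boundaries are excluded to suppress filter transients.
    """
    steer = np.asarray(steer_filtered_deg, dtype=float)
    mask = np.asarray(mask, dtype=bool) & _edge_mask(len(steer), fs_hz)
    if not mask.any():
        raise ValueError("steering-activity mask selects no samples")
    rate = np.gradient(steer, 1.0 / fs_hz)
    return float(np.mean(np.abs(rate[mask])))


def sdlp(y_m: np.ndarray, mask: np.ndarray) -> float:
    """Standard deviation of lateral position (m), n−1 denominator."""
    y = np.asarray(y_m, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("SDLP mask selects no samples")
    return float(np.std(y[mask], ddof=1))


def _interp_y_at(trace: SessionTrace, s: float) -> float:
    return float(np.interp(s, trace.s_m, trace.y_m))


def long_dto(trace: SessionTrace, obstacle_s: float,
             road_center_y: float = ROAD_CENTER_Y_M,
             window_before_m: float = 150.0) -> float | None:
    """Longitudinal distance to the obstacle at lane-change commitment.

    The commitment point is the last upward crossing of the road centre
    (y = 1.8 m) within the 150 m before the obstacle after which the
    vehicle stays left of the centre line until the obstacle.  Crossing
    position is linearly interpolated between samples.  ``None`` when
    the vehicle never commits (no crossing).
    """
    s, y = trace.s_m, trace.y_m
    if not (s[0] <= obstacle_s <= s[-1]):
        raise ValueError("obstacle outside the trace span")
    sel = (s >= obstacle_s - window_before_m) & (s <= obstacle_s)
    idx = np.flatnonzero(sel)
    if len(idx) < 2:
        return None
    ss, yy = s[idx], y[idx]
    up = np.flatnonzero((yy[:-1] < road_center_y) & (yy[1:] >= road_center_y))
    committed = [
        i for i in up
        if np.all(yy[i + 1:] >= road_center_y)
    ]
    if not committed:
        # also covers the case of entering the window already left of centre
        return None
    i = committed[-1]
    frac = (road_center_y - yy[i]) / (yy[i + 1] - yy[i])
    s_cross = ss[i] + frac * (ss[i + 1] - ss[i])
    return float(obstacle_s - s_cross)


def lat_dto(trace: SessionTrace, obstacle_s: float) -> float:
    """Lateral clearance |y| (m) when passing the obstacle (at y = 0)."""
    if not (trace.s_m[0] <= obstacle_s <= trace.s_m[-1]):
        raise ValueError("obstacle outside the trace span")
    return abs(_interp_y_at(trace, obstacle_s))


def detect_collisions(trace: SessionTrace,
                      obstacle_positions_m: np.ndarray | list[float],
                      car_length_m: float = CAR_LENGTH_M,
                      obstacle_lengths_m: list[float] | None = None,
                      ) -> tuple[int, list[bool]]:
    """Collision flags per obstacle and their count.

    A collision is a lateral clearance strictly below 1.6 m at any
    sample where the vehicle drives alongside the obstacle, i.e. where
    the centre-to-centre longitudinal distance is at most half the sum
    of the car and obstacle lengths.
    """
    obstacle_positions_m = np.asarray(obstacle_positions_m, dtype=float)
    if obstacle_lengths_m is None:
        obstacle_lengths_m = list(DEFAULT_OBSTACLE_LENGTHS_M[:len(obstacle_positions_m)])
    flags: list[bool] = []
    for pos, olen in zip(obstacle_positions_m, obstacle_lengths_m):
        alongside = np.abs(trace.s_m - pos) <= (car_length_m + olen) / 2.0
        hit = bool(alongside.any()
                   and np.min(np.abs(trace.y_m[alongside])) < COLLISION_LATERAL_M)
        flags.append(hit)
    return sum(flags), flags


def _distance_masks(trace: SessionTrace, course: CourseSpec
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(obstacle-period mask, non-obstacle mask) over trace samples."""
    merged = merge_intervals(obstacle_windows(course))
    in_win = np.zeros(len(trace.s_m), dtype=bool)
    for lo, hi in merged:
        in_win |= (trace.s_m >= lo) & (trace.s_m <= hi)
    return in_win, ~in_win


def session_driving_metrics(trace: SessionTrace, course: CourseSpec,
                            session_id: str | None = None) -> DrivingMetrics:
    """All Table-2 style driving measures for one session trace.

    SA-high/SA-low are reported inside and outside the obstacle
    windows in every session, whether or not obstacles were present;
    SDLP uses the non-obstacle sections; obstacle-avoidance measures
    (LongDtO, LatDtO, collisions) apply to the obstacle sessions S3/S4.
    """
    sid = session_id or trace.session_id
    obst_mask, free_mask = _distance_masks(trace, course)
    steer_hi = lowpass(trace.steer_deg, 2.0)
    steer_lo = lowpass(trace.steer_deg, 0.5)
    m = DrivingMetrics(
        session_id=sid,
        sa_high_nonobstacle=steering_activity(steer_hi, free_mask),
        sa_high_obstacle=steering_activity(steer_hi, obst_mask),
        sa_low_nonobstacle=steering_activity(steer_lo, free_mask),
        sa_low_obstacle=steering_activity(steer_lo, obst_mask),
        sdlp_nonobstacle=sdlp(trace.y_m, free_mask),
    )
    if sid in ("S3", "S4"):
        reachable = [p for p in course.obstacle_positions_m
                     if trace.s_m[0] <= p <= trace.s_m[-1]]
        m.long_dto_m = [long_dto(trace, p, window_before_m=course.obstacle_window_before_m)
                        for p in reachable]
        m.lat_dto_m = [lat_dto(trace, p) for p in reachable]
        m.collisions, m.collision_flags = detect_collisions(trace, reachable)
    return m
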