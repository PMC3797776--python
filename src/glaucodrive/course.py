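"""Deterministic model of the experimental driving course.

The course is a two-lane highway driven at a fixed, automatically
controlled speed.  The car accelerates during the first seconds of a
session and then cruises at 100 km/h; nine static obstacles sit in the
right lane at known longitudinal positions, and in the letter-task
sessions 32 letters are projected on the screen at preprogrammed
positions.  Everything here is kinematic: position along the course as a
function of time, obstacle encounter times, obstacle analysis windows,
and the randomised letter schedule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from collections.abc import Sequence
from typing import Callable

import numpy as np

__all__ = [
    "CourseSpec",
    "LetterScheduleSpec",
    "LetterEvent",
    "default_accel_profile",
    "position_at_time",
    "encounter_time",
    "generate_letter_schedule",
    "obstacle_windows",
    "merge_intervals",
    "default_letter_positions_mm",
    "DEFAULT_EYE_POINT_MM",
]

KMH_100_MPS = 100.0 / 3.6  # cruise speed, m/s

#: Driver eye point relative to the screen, mm: (x from screen left edge,
#: y from screen bottom edge, perpendicular viewing distance).
DEFAULT_EYE_POINT_MM = (150.0, 350.0, 780.0)


@dataclass(frozen=True)
class CourseSpec:
    """Geometry and schedule constants of the simulator course."""

    length_m: float = 7534.0
    lane_width_m: float = 3.6
    n_lanes: int = 2
    session_duration_s: float = 278.0
    cruise_speed_mps: float = KMH_100_MPS
    cruise_reached_s: float = 17.0
    obstacle_positions_m: tuple[float, ...] = (
        350.0, 1171.0, 1521.0, 2125.0, 3193.0, 3563.0, 6095.0, 6395.0, 7262.0
    )
    obstacle_window_before_m: float = 150.0
    obstacle_window_after_m: float = 200.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.obstacle_positions_m, dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError("obstacle positions must be strictly increasing")
        if pos.size and pos[-1] >= self.length_m:
            raise ValueError("obstacle positions must lie within the course")
        if self.obstacle_window_before_m < 0 or self.obstacle_window_after_m < 0:
            raise ValueError("obstacle windows must be non-negative")

    def to_json(self) -> str:
        return json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, indent=2
        )


def default_accel_profile(t: float, *, distance_at_cruise_m: float = 275.0,
                          cruise_reached_s: float = 17.0,
                          cruise_speed_mps: float = KMH_100_MPS) -> float:
    """Distance covered during the automatic acceleration phase.

    Monotone on [0, cruise_reached_s], with a fast initial pull-away so
    that the distance at cruise onset equals ``distance_at_cruise_m``
    (default 275 m, i.e. the first obstacle at 350 m is met 2.7 s into
    the cruise phase) and the speed is continuous at the cruise boundary.
    Quadratic in t: f(t) = a·t + b·t², with f(T) fixed and f'(T) equal to
    the cruise speed.
    """
    T, D, v = cruise_reached_s, distance_at_cruise_m, cruise_speed_mps
    b = (D - v * T) / (-T * T)  # from f(T)=D, f'(T)=v
    a = v - 2.0 * b * T
    if a < 0:
        raise ValueError("acceleration profile is not monotone for these constants")
    return a * t + b * t * t


def position_at_time(spec: CourseSpec, t: float,
                     accel_profile: Callable[[float], float] | None = None) -> float:
    """Longitudinal position (m) along the course at session time ``t``.

    Before ``cruise_reached_s`` the configurable monotone acceleration
    profile applies; afterwards the car covers ground at the constant
    cruise speed.
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    profile = accel_profile if accel_profile is not None else (
        lambda u: default_accel_profile(
            u, cruise_reached_s=spec.cruise_reached_s,
            cruise_speed_mps=spec.cruise_speed_mps)
    )
    if t < spec.cruise_reached_s:
        return profile(t)
    return profile(spec.cruise_reached_s) + (t - spec.cruise_reached_s) * spec.cruise_speed_mps


def encounter_time(spec: CourseSpec, obstacle_index: int,
                   reference: tuple[float, float],
                   accel_profile: Callable[[float], float] | None = None) -> float:
    """Time at which the car reaches obstacle ``obstacle_index`` (1-based).

    ``reference`` is a known (time_s, position_m) anchor inside the
    constant-speed phase; the obstacle time follows from dead reckoning
    at the cruise speed.
    """
    if not 1 <= obstacle_index <= len(spec.obstacle_positions_m):
        raise ValueError(f"obstacle index {obstacle_index} out of range")
    ref_t, ref_s = reference
    if ref_t < spec.cruise_reached_s:
        raise ValueError("reference time must lie in the constant-speed phase")
    obstacle_s = spec.obstacle_positions_m[obstacle_index - 1]
    if obstacle_s < ref_s:
        raise ValueError("obstacle lies before the reference position")
    return ref_t + (obstacle_s - ref_s) / spec.cruise_speed_mps


def merge_intervals(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping/touching (start, end) intervals."""
    out: list[tuple[float, float]] = []
    for lo, hi in sorted(intervals):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def obstacle_windows(spec: CourseSpec, merged: bool = False) -> list[tuple[float, float]]:
    """Per-obstacle analysis windows [pos − 150 m, pos + 200 m].

    With ``merged=True``, overlapping windows are merged, which is the
    form used to build the non-obstacle-period complement.
    """
    wins = [
        (p - spec.obstacle_window_before_m, p + spec.obstacle_window_after_m)
        for p in spec.obstacle_positions_m
    ]
    return merge_intervals(wins) if merged else wins


# ---------------------------------------------------------------------------
# Letter schedule
# ---------------------------------------------------------------------------

def default_letter_positions_mm(
    eye_point_mm: tuple[float, float, float] = DEFAULT_EYE_POINT_MM,
    h_angles_deg: Sequence[float] = (-6.4, 1.5, 9.5, 18.5, 36.1),
    v_angles_deg: Sequence[float] = (-2.9, 2.0, 7.0, 12.0, 16.8),
    ) -> np.ndarray:
    """25 preprogrammed letter positions on the screen, mm.

    A 5 × 5 grid in visual angle from the driver's eye point whose
    extreme columns/rows match the estimated eccentricities of the
    leftmost (−6.4°), rightmost (36.1°), lowest (−2.9°) and highest
    (16.8°) projected letters.  The columns bunch toward the road
    region with one far-peripheral column on the right, so that only
    the rightmost letters fall outside the ~21° integrated-field
    margin.  Returns an (n, 2) array of (x_mm, y_mm), origin at the
    screen's bottom-left corner.
    """
    ex, ey, d = eye_point_mm
    h = np.deg2rad(np.asarray(h_angles_deg, dtype=float))
    v = np.deg2rad(np.asarray(v_angles_deg, dtype=float))
    xs = ex + d * np.tan(h)
    ys = ey + d * np.tan(v)
    return np.array([(x, y) for y in ys for x in xs])


@dataclass(frozen=True)
class LetterScheduleSpec:
    """Timing and layout constraints of the letter-verbalisation task."""

    n_letters: int = 32
    n_positions: int = 25
    first_onset_s: float = 6.0
    display_duration_s: float = 4.0
    gap_range_s: tuple[float, float] = (3.0, 6.0)
    session_duration_s: float = 278.0
    positions_mm: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: tuple(map(tuple, default_letter_positions_mm()))
    )

    def __post_init__(self) -> None:
        if len(self.positions_mm) != self.n_positions:
            raise ValueError("positions_mm length must equal n_positions")
        min_span = (self.first_onset_s
                    + (self.n_letters - 1) * (self.display_duration_s + self.gap_range_s[0])
                    + self.display_duration_s)
        if min_span > self.session_duration_s:
            raise ValueError("letter schedule cannot fit in the session")


@dataclass(frozen=True)
class LetterEvent:
    letter_id: int
    onset_s: float
    offset_s: float
    x_mm: float
    y_mm: float


def generate_letter_schedule(spec: LetterScheduleSpec,
                             rng_seed: int | np.random.Generator) -> list[LetterEvent]:
    """Randomised letter schedule: onsets, offsets and screen positions.

    The first letter appears at ``first_onset_s``; each letter stays on
    for ``display_duration_s``; the gap between a letter's disappearance
    and the next appearance is uniform in ``gap_range_s``.  Schedules
    whose last offset would overrun the session are resampled.
    Positions are drawn from the 25 preprogrammed coordinates, each used
    at least once across the 32 letters.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    n, dur = spec.n_letters, spec.display_duration_s
    for _ in range(1000):
        gaps = rng.uniform(*spec.gap_range_s, size=n - 1)
        onsets = spec.first_onset_s + np.concatenate(
            ([0.0], np.cumsum(dur + gaps)))
        if onsets[-1] + dur <= spec.session_duration_s:
            break
    else:  # pragma: no cover - bound guaranteed by spec validation
        raise ValueError("could not sample a feasible letter schedule")
    pos_idx = np.concatenate([
        rng.permutation(spec.n_positions),
        rng.choice(spec.n_positions, size=n - spec.n_positions, replace=False),
    ])[:n]
    positions = np.asarray(spec.positions_mm)
    return [
        LetterEvent(i + 1, float(t), float(t + dur),
                    float(positions[j, 0]), float(positions[j, 1]))
        for i, (t, j) in enumerate(zip(onsets, pos_idx))
    ]


def eccentricity_deg(x_mm: float, y_mm: float,
                     anchor_mm: tuple[float, float],
                     viewing_distance_mm: float) -> float:
    """Angular eccentricity (deg) of a screen point from a gaze anchor."""
    dx = x_mm - anchor_mm[0]
    dy = y_mm - anchor_mm[1]
    return math.degrees(math.atan(math.hypot(dx, dy) / viewing_distance_mm))
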