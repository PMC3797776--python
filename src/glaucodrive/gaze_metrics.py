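"""Gaze preprocessing and eye-scanning measures.

The raw eye-tracker stream (60 Hz screen coordinates with a validity
flag) is cleaned by removing blinks with a ±0.5 s margin, dropping
invalid samples, and discarding any surviving segment shorter than 1 s;
each retained segment is lowpass filtered (2nd-order Butterworth,
20 Hz, zero phase).  A participant whose removed fraction exceeds 60 %
in any session is excluded from eye-scanning analyses entirely.

Fixations are identified with the dispersion-threshold algorithm
(I-DT): a window of at least 150 ms whose dispersion — horizontal
extent plus vertical extent, converted to visual degrees via the
viewing distance — stays within 3° is grown as far as possible and
emitted as one fixation at the window centroid.  Derived measures are
fixations per second of retained time, mean saccade amplitude (distance
between consecutive fixation centroids within a segment, mm), and the
percentage of retained samples inside named screen regions (top/bottom
bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "GazeStream",
    "GazeSegment",
    "CleanGaze",
    "Fixation",
    "preprocess",
    "detect_fixations",
    "fixation_rate",
    "saccade_amplitude",
    "region_dwell",
    "default_regions",
    "SCREEN_W_MM",
    "SCREEN_H_MM",
    "VIEWING_DISTANCE_MM",
]

SAMPLE_RATE_HZ = 60.0
SCREEN_W_MM = 1090.0
SCREEN_H_MM = 770.0
#: Perpendicular eye–screen distance giving the simulator's ~70° horizontal
#: field of view over the 1.09 m screen.
VIEWING_DISTANCE_MM = 780.0
BLINK_MARGIN_S = 0.5
MIN_SEGMENT_S = 1.0
EXCLUSION_THRESHOLD = 0.6
DISPERSION_DEG = 3.0
MIN_FIXATION_S = 0.15
GAZE_FILTER_CUTOFF_HZ = 20.0


@dataclass
class GazeStream:
    """Raw 60 Hz gaze samples on the screen (origin bottom-left, mm)."""

    t: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if any(len(a) != n for a in (self.x_mm, self.y_mm, self.valid)):
            raise ValueError("gaze columns must have equal length")
        if n > 1 and not np.allclose(np.diff(self.t), 1.0 / SAMPLE_RATE_HZ,
                                     atol=1e-6):
            raise ValueError("gaze stream must be uniformly sampled at 60 Hz")


@dataclass
class GazeSegment:
    t: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray


@dataclass
class CleanGaze:
    segments: list[GazeSegment]
    removed_fraction: float
    session_duration_s: float
    excluded: bool = False

    @property
    def retained_duration_s(self) -> float:
        return sum(len(s.t) for s in self.segments) / SAMPLE_RATE_HZ

    @property
    def n_retained_samples(self) -> int:
        return sum(len(s.t) for s in self.segments)


@dataclass
class Fixation:
    start_s: float
    end_s: float
    cx_mm: float
    cy_mm: float
    segment_index: int = 0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def preprocess(raw: GazeStream,
               exclusion_threshold: float = EXCLUSION_THRESHOLD,
               blink_margin_s: float = BLINK_MARGIN_S,
               min_segment_s: float = MIN_SEGMENT_S,
               filter_cutoff_hz: float = GAZE_FILTER_CUTOFF_HZ) -> CleanGaze:
    """Blink/segment exclusion and per-segment lowpass filtering.

    Blinks are maximal runs of invalid samples; samples within
    ``blink_margin_s`` before and after each run are removed along with
    the run itself, then any retained segment shorter than
    ``min_segment_s`` is dropped.  The removed fraction is measured
    against the full session duration.
    """
    n = len(raw.t)
    keep = raw.valid.copy()
    margin = int(round(blink_margin_s * SAMPLE_RATE_HZ))
    for start, stop in _runs(~raw.valid):
        keep[max(0, start - margin):min(n, stop + margin)] = False
    min_len = int(round(min_segment_s * SAMPLE_RATE_HZ))
    segments: list[GazeSegment] = []
    for start, stop in _runs(keep):
        if stop - start < min_len:
            keep[start:stop] = False
            continue
        x = raw.x_mm[start:stop]
        y = raw.y_mm[start:stop]
        if filter_cutoff_hz and filter_cutoff_hz < SAMPLE_RATE_HZ / 2:
            b, a = signal.butter(2, filter_cutoff_hz, fs=SAMPLE_RATE_HZ)
            padlen = 3 * (max(len(a), len(b)) - 1)
            if stop - start > padlen:
                x = signal.filtfilt(b, a, x)
                y = signal.filtfilt(b, a, y)
        segments.append(GazeSegment(raw.t[start:stop], x, y))
    removed = 1.0 - keep.sum() / n
    clean = CleanGaze(segments=segments, removed_fraction=float(removed),
                      session_duration_s=n / SAMPLE_RATE_HZ)
    clean.excluded = bool(removed > exclusion_threshold)
    return clean


def participant_excluded(cleans: list[CleanGaze],
                         exclusion_threshold: float = EXCLUSION_THRESHOLD) -> bool:
    """Whole-participant exclusion: any session over the removal limit."""
    return any(c.removed_fraction > exclusion_threshold for c in cleans)


def mm_to_deg(extent_mm: float,
              viewing_distance_mm: float = VIEWING_DISTANCE_MM) -> float:
    """Small-angle conversion of an on-screen extent to visual degrees."""
    return float(np.degrees(extent_mm / viewing_distance_mm))


def detect_fixations(clean: CleanGaze,
                     dispersion_deg: float = DISPERSION_DEG,
                     min_dur_s: float = MIN_FIXATION_S,
                     viewing_distance_mm: float = VIEWING_DISTANCE_MM
                     ) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation identification.

    Within each retained segment, a candidate window of
    ``min_dur_s`` is tested; if its dispersion (x-extent + y-extent,
    in degrees at the viewing distance) is within threshold it is grown
    sample by sample until the dispersion would exceed it, then emitted
    as a fixation at the window centroid.  Windows never span segment
    gaps.
    """
    if viewing_distance_mm <= 0:
        raise ValueError("viewing distance must be positive")
    thr_mm = np.radians(dispersion_deg) * viewing_distance_mm
    w = int(round(min_dur_s * SAMPLE_RATE_HZ))
    out: list[Fixation] = []
    for si, seg in enumerate(clean.segments):
        x, y, t = seg.x_mm, seg.y_mm, seg.t
        n = len(x)
        i = 0
        while i + w <= n:
            xw, yw = x[i:i + w], y[i:i + w]
            xmin, xmax = xw.min(), xw.max()
            ymin, ymax = yw.min(), yw.max()
            if (xmax - xmin) + (ymax - ymin) > thr_mm:
                i += 1
                continue
            j = i + w
            while j < n:
                nxmin = min(xmin, x[j]); nxmax = max(xmax, x[j])
                nymin = min(ymin, y[j]); nymax = max(ymax, y[j])
                if (nxmax - nxmin) + (nymax - nymin) > thr_mm:
                    break
                xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
                j += 1
            # each sample covers one 1/60 s frame, so the window's span is
            # (j - i)/60 s and a minimal window meets the 150 ms duration
            out.append(Fixation(
                start_s=float(t[i]), end_s=float(t[j - 1]) + 1.0 / SAMPLE_RATE_HZ,
                cx_mm=float(x[i:j].mean()), cy_mm=float(y[i:j].mean()),
                segment_index=si))
            i = j
    return out


def fixation_rate(fixations: list[Fixation], clean: CleanGaze) -> float:
    """Fixations per second of retained recording time."""
    dur = clean.retained_duration_s
    if dur <= 0:
        raise ValueError("no retained gaze data")
    return len(fixations) / dur


def saccade_amplitude(fixations: list[Fixation]) -> float | None:
    """Mean distance (mm) between consecutive fixation centroids.

    Pairs spanning a removed gap (different retained segments) are not
    counted.  ``None`` when no eligible pair exists.
    """
    dists = [
        float(np.hypot(b.cx_mm - a.cx_mm, b.cy_mm - a.cy_mm))
        for a, b in zip(fixations, fixations[1:])
        if a.segment_index == b.segment_index
    ]
    return float(np.mean(dists)) if dists else None


def default_regions(band_fraction: float = 0.2) -> dict[str, tuple[float, float, float, float]]:
    """Top/bottom full-width screen bands (x0, y0, x1, y1), mm."""
    h = SCREEN_H_MM
    return {
        "top": (0.0, (1 - band_fraction) * h, SCREEN_W_MM, h),
        "bottom": (0.0, 0.0, SCREEN_W_MM, band_fraction * h),
    }


def region_dwell(clean: CleanGaze,
                 regions: dict[str, tuple[float, float, float, float]] | None = None
                 ) -> dict[str, float]:
    """Percentage of retained samples inside each named screen region."""
    regions = regions if regions is not None else default_regions()
    for name, (x0, y0, x1, y1) in regions.items():
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"degenerate region {name!r}")
    total = clean.n_retained_samples
    out = {}
    for name, (x0, y0, x1, y1) in regions.items():
        inside = sum(
            int(np.sum((s.x_mm >= x0) & (s.x_mm <= x1)
                       & (s.y_mm >= y0) & (s.y_mm <= y1)))
            for s in clean.segments)
        out[name] = 100.0 * inside / total if total else float("nan")
    return out
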