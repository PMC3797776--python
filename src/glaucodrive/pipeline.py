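"""End-to-end orchestration: participant records → measures → tables.

Collapses each participant's raw streams into the per-participant
summary measures the study tables use (driving measures averaged over
sessions, pooled letter misses and reaction time, eye-scanning measures
averaged over sessions, quadrant sensitivity-loss percentages, TLX
total), and builds the patient-only correlation table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_sim import (ParticipantRecord, SESSIONS, LETTER_SESSIONS,
                         OBSTACLE_SESSIONS)
from .course import CourseSpec
from .driving_metrics import session_driving_metrics
from .gaze_metrics import (preprocess, detect_fixations, fixation_rate,
                           saccade_amplitude, region_dwell,
                           participant_excluded)
from .letter_scoring import (score_letters, session_letter_summary,
                             letter_vf_correlations)
from .stats_report import tlx_total, build_report
from .visual_field import quadrant_loss, better_worse_eye

__all__ = [
    "participant_measures",
    "cohort_measures",
    "patient_correlation_table",
    "analyze_cohort",
]


def _nanmean(vals) -> float:
    vals = [v for v in vals if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def participant_measures(rec: ParticipantRecord,
                         course: CourseSpec | None = None) -> dict:
    """One row of study-style summary measures for a participant."""
    course = course or CourseSpec()
    p = rec.profile
    row: dict = {"id": p.id, "group": p.group,
                 "scotoma_pattern": p.scotoma_pattern, "age": p.age_years}

    if rec.ivf is not None:
        row["ivf_loss_pct"] = 100.0 * float(
            np.mean(rec.ivf.sensitivity_db < 25.0))
        for q, v in rec.ivf.quadrant_loss_pct.items():
            row[f"ivf_{q}"] = v
        better, worse = better_worse_eye(rec.vf_od, rec.vf_os)
        for label, vf in (("better", better), ("worse", worse)):
            for q, v in quadrant_loss(vf).items():
                row[f"{label}_{q}"] = v
        row["md_od"] = rec.vf_od.md_db
        row["md_os"] = rec.vf_os.md_db

    if rec.traces:
        per_session = {sid: session_driving_metrics(tr, course, sid)
                       for sid, tr in rec.traces.items()}
        row["sdlp_nonobstacle"] = _nanmean(
            m.sdlp_nonobstacle for m in per_session.values())
        row["sa_high_nonobstacle"] = _nanmean(
            m.sa_high_nonobstacle for m in per_session.values())
        row["sa_low_nonobstacle"] = _nanmean(
            m.sa_low_nonobstacle for m in per_session.values())
        obst = [per_session[s] for s in OBSTACLE_SESSIONS if s in per_session]
        row["sa_high_obstacle"] = _nanmean(m.sa_high_obstacle for m in obst)
        row["sa_low_obstacle"] = _nanmean(m.sa_low_obstacle for m in obst)
        row["long_dto_mean"] = _nanmean(m.long_dto_mean for m in obst)
        row["lat_dto_mean"] = _nanmean(m.lat_dto_mean for m in obst)
        row["collisions"] = int(sum(m.collisions for m in obst))

    if rec.events:
        scores = [score_letters(rec.events[s].letters,
                                rec.events[s].voice_events)
                  for s in LETTER_SESSIONS if s in rec.events]
        misses, lrt = session_letter_summary(scores)
        row["misses"] = misses
        row["lrt_s"] = lrt if lrt is not None else np.nan

    if rec.gaze:
        cleans = {sid: preprocess(g) for sid, g in rec.gaze.items()}
        row["eye_excluded"] = participant_excluded(list(cleans.values()))
        rates, amps, tops, bottoms = [], [], [], []
        for clean in cleans.values():
            if clean.n_retained_samples == 0:
                continue
            fixes = detect_fixations(clean)
            rates.append(fixation_rate(fixes, clean))
            amp = saccade_amplitude(fixes)
            if amp is not None:
                amps.append(amp)
            dwell = region_dwell(clean)
            tops.append(dwell["top"])
            bottoms.append(dwell["bottom"])
        row["fixations_per_s"] = _nanmean(rates)
        row["saccade_amplitude_mm"] = _nanmean(amps)
        row["dwell_top_pct"] = _nanmean(tops)
        row["dwell_bottom_pct"] = _nanmean(bottoms)

    if rec.tlx:
        row["tlx_total_pct"] = _nanmean(
            tlx_total(items) for items in rec.tlx.values())
        for sid in SESSIONS:
            if sid in rec.tlx:
                row[f"tlx_{sid}_pct"] = tlx_total(rec.tlx[sid])
    return row


def cohort_measures(records: list[ParticipantRecord],
                    course: CourseSpec | None = None) -> pd.DataFrame:
    """Per-participant measure table for a whole cohort."""
    return pd.DataFrame([participant_measures(r, course) for r in records])


def patient_correlation_table(measures: pd.DataFrame) -> pd.DataFrame:
    """Quadrant-loss vs letter-performance Spearman table, patients only."""
    patients = measures[measures.group == "glaucoma"]
    return letter_vf_correlations(patients)


def analyze_cohort(records: list[ParticipantRecord],
                   course: CourseSpec | None = None
                   ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Measures table plus the five study-style report tables."""
    measures = cohort_measures(records, course)
    corr = None
    needed = {"misses", "lrt_s", "ivf_UL"}
    if needed <= set(measures.columns) and \
            (measures.group == "glaucoma").sum() >= 5:
        corr = patient_correlation_table(measures)
    return measures, build_report(measures, corr)
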