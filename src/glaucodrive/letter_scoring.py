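"""Scoring of the peripheral letter-verbalisation task.

A letter counts as detected if any voice event falls between its onset
and one second after its disappearance (i.e. within [onset, offset + 1 s]);
the reaction time (LRT) is the elapsed time from onset to the voice
event.  Letters without an assigned voice event are misses.  The study
summary pools sessions S2 and S4: total misses and the mean LRT over
all detected letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .course import LetterEvent
from .stats_report import spearman

__all__ = [
    "LetterScore",
    "score_letters",
    "session_letter_summary",
    "letter_vf_correlations",
    "DETECTION_GRACE_S",
]

DETECTION_GRACE_S = 1.0
RESPONSE_WINDOW_S = 5.0  # display 4 s + 1 s grace


@dataclass
class LetterScore:
    """Per-letter detection outcomes and session summary for one session."""

    per_letter: pd.DataFrame  # letter_id, onset_s, detected, voice_t, rt_s
    spurious_voice_events: list[float] = field(default_factory=list)

    @property
    def n_misses(self) -> int:
        return int((~self.per_letter.detected).sum())

    @property
    def n_detected(self) -> int:
        return int(self.per_letter.detected.sum())

    @property
    def mean_lrt_s(self) -> float | None:
        rts = self.per_letter.rt_s.dropna()
        return float(rts.mean()) if len(rts) else None


def score_letters(letters: Sequence[LetterEvent],
                  voice_events: Sequence[float],
                  grace_s: float = DETECTION_GRACE_S) -> LetterScore:
    """Assign voice events to letters and classify detections and misses.

    Greedy one-to-one matching, earliest-onset letter first: each letter
    takes the first unassigned voice event inside its window
    [onset, offset + grace].  With the study's 3–6 s inter-letter gaps
    the windows cannot overlap, so the greedy match is exact.  Surplus
    voice events (including any before the first onset) are logged as
    spurious, not scored.
    """
    letters = sorted(letters, key=lambda ev: ev.onset_s)
    voices = sorted(float(v) for v in voice_events)
    assigned = [False] * len(voices)
    rows = []
    for ev in letters:
        hit_t, hit_rt = np.nan, np.nan
        detected = False
        for j, v in enumerate(voices):
            if assigned[j] or v < ev.onset_s:
                continue
            if v > ev.offset_s + grace_s:
                break
            assigned[j] = True
            detected, hit_t, hit_rt = True, v, v - ev.onset_s
            break
        rows.append((ev.letter_id, ev.onset_s, detected, hit_t, hit_rt))
    per_letter = pd.DataFrame(
        rows, columns=["letter_id", "onset_s", "detected", "voice_t", "rt_s"])
    spurious = [v for v, a in zip(voices, assigned) if not a]
    return LetterScore(per_letter=per_letter, spurious_voice_events=spurious)


def session_letter_summary(scores: Sequence[LetterScore]
                           ) -> tuple[int, float | None]:
    """Pooled (total misses, mean LRT) over the letter sessions (S2, S4).

    Misses are summed; the LRT is averaged over every detected letter in
    the pooled sessions (``None`` if nothing was detected).
    """
    misses = sum(s.n_misses for s in scores)
    rts = pd.concat([s.per_letter.rt_s for s in scores]).dropna()
    return misses, (float(rts.mean()) if len(rts) else None)


def letter_vf_correlations(patients: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations of visual-field loss with letter performance.

    ``patients`` holds one row per glaucoma patient with columns
    ``misses``, ``lrt_s`` and quadrant-loss percentages named
    ``{field}_{quadrant}`` for field in {ivf, worse, better} and
    quadrant in {UL, UR, LL, LR}.  Returns a 12-row table
    (vf_location, vf_type, rho_misses, p_misses, rho_lrt, p_lrt);
    zero-variance columns yield NaN rho with a flag.
    """
    if len(patients) < 5:
        raise ValueError("need at least 5 patients for the correlation table")
    rows = []
    for quad in ("UL", "UR", "LL", "LR"):
        for ftype, label in (("ivf", "IVF"), ("worse", "Worse eye"),
                             ("better", "Better eye")):
            loss = patients[f"{ftype}_{quad}"].to_numpy(dtype=float)
            row = {"vf_location": quad, "vf_type": label}
            for meas, col in (("misses", "misses"), ("lrt", "lrt_s")):
                y = patients[col].to_numpy(dtype=float)
                ok = np.isfinite(loss) & np.isfinite(y)
                if ok.sum() < 3 or np.ptp(loss[ok]) == 0 or np.ptp(y[ok]) == 0:
                    rho, p = np.nan, np.nan
                else:
                    rho, p = spearman(loss[ok], y[ok])
                row[f"rho_{meas}"], row[f"p_{meas}"] = rho, p
            rows.append(row)
    return pd.DataFrame(rows)
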