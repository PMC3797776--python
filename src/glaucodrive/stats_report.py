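"""Group statistics, NASA-TLX scoring, and study-style report tables.

Group comparisons use Welch's two-sample t-test (unequal variances,
Welch–Satterthwaite degrees of freedom); session contrasts use a paired
t-test; associations use Spearman rank correlation with midrank ties.
All tests are two-tailed at α = 0.05 and no multiple-testing correction
is applied (the study argued that with a small sample, lowering α would
disproportionately inflate the false-negative rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "welch_t",
    "paired_t",
    "spearman",
    "tlx_total",
    "build_report",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    measure: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return bool(self.p < self.alpha)


def welch_t(a, b, measure: str = "") -> GroupComparison:
    """Welch's unequal-variance two-sample t-test, two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 finite values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        measure=measure,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b),
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
    )


def paired_t(before, after, measure: str = "") -> GroupComparison:
    """Paired t-test on before/after differences, df = n − 1, two-tailed.

    A constant nonzero shift with zero difference variance yields an
    infinite statistic and p = 0 (flagged by ``t = ±inf``).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    if len(before) < 2:
        raise ValueError("need at least 2 pairs")
    d = after - before
    n = len(d)
    if np.std(d, ddof=1) == 0:
        t = 0.0 if d.mean() == 0 else float(np.sign(d.mean()) * np.inf)
        p = 1.0 if d.mean() == 0 else 0.0
    else:
        res = sps.ttest_rel(after, before)
        t, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        measure=measure,
        mean_a=float(before.mean()), sd_a=float(before.std(ddof=1)), n_a=n,
        mean_b=float(after.mean()), sd_b=float(after.std(ddof=1)), n_b=n,
        t=t, df=float(n - 1), p=p,
    )


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) and two-tailed p.

    The p-value uses the t approximation, the common choice at these
    sample sizes; ``exact=True`` switches to a full permutation p-value
    (only for n ≤ 10).  Zero rank variance raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(sps.rankdata(x)) == 0 or np.ptp(sps.rankdata(y)) == 0:
        raise ValueError("zero rank variance; correlation undefined")
    rho = float(sps.spearmanr(x, y).statistic)
    n = len(x)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        obs = abs(rho)
        count = total = 0
        for perm in permutations(y):
            r = float(sps.spearmanr(x, perm).statistic)
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, p


TLX_ITEMS = ("mental", "physical", "temporal", "performance",
             "effort", "frustration")


def tlx_total(items) -> float:
    """NASA-TLX total workload as a 0–100 % score.

    Items are the six subscale ratings on the 21-tick bar (1 = very
    low … 21 = very high); the total is the item mean rescaled so that
    all-1 ratings give 0 % and all-21 give 100 %.
    """
    vals = np.asarray(
        [items[k] for k in TLX_ITEMS] if isinstance(items, dict) else items,
        dtype=float)
    if vals.shape != (6,):
        raise ValueError("TLX rating needs exactly six items")
    if np.any((vals < 1) | (vals > 21)):
        raise ValueError("TLX items must lie in [1, 21]")
    return float(100.0 * (vals.mean() - 1.0) / 20.0)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _compare_rows(df: pd.DataFrame, measures: dict[str, str]) -> pd.DataFrame:
    """Welch comparisons control vs glaucoma for the given columns."""
    rows = []
    ctrl = df[df.group == "control"]
    pat = df[df.group == "glaucoma"]
    for col, label in measures.items():
        a = ctrl[col].dropna()
        b = pat[col].dropna()
        if len(a) < 2 or len(b) < 2:
            rows.append({"measure": label, "control_mean": np.nan,
                         "control_sd": np.nan, "glaucoma_mean": np.nan,
                         "glaucoma_sd": np.nan, "n_control": len(a),
                         "n_glaucoma": len(b), "t": np.nan, "df": np.nan,
                         "p": np.nan, "significant": False})
            continue
        c = welch_t(a, b, measure=label)
        rows.append({
            "measure": label,
            "control_mean": c.mean_a, "control_sd": c.sd_a,
            "glaucoma_mean": c.mean_b, "glaucoma_sd": c.sd_b,
            "n_control": c.n_a, "n_glaucoma": c.n_b,
            "t": c.t, "df": c.df, "p": c.p, "significant": c.significant,
        })
    return pd.DataFrame(rows)


DRIVING_MEASURES = {
    "sdlp_nonobstacle": "Standard deviation of lateral position (SDLP), non-obstacle periods (S1-S4) (m)",
    "sa_high_nonobstacle": "Steering Activity-high, non-obstacle periods (S1-S4) (deg/s)",
    "sa_high_obstacle": "Steering Activity-high, obstacle periods (S3,S4) (deg/s)",
    "sa_low_nonobstacle": "Steering Activity-low, non-obstacle periods (S1-S4) (deg/s)",
    "sa_low_obstacle": "Steering Activity-low, obstacle periods (S3,S4) (deg/s)",
    "long_dto_mean": "Longitudinal distance to obstacle (LongDtO) (S3, S4) (m)",
    "lat_dto_mean": "Lateral position to obstacle (LatDtO) (S3, S4) (m)",
}

LETTER_MEASURES = {
    "lrt_s": "Letter Reaction Time (LRT) (S2, S4) (s)",
    "misses": "Number of letter misses (S2, S4)",
}

EYE_MEASURES = {
    "dwell_top_pct": "Gaze directed at top (S1-S4) (% of time)",
    "dwell_bottom_pct": "Gaze directed at bottom (S1-S4) (% of time)",
    "fixations_per_s": "Number of fixations per second (S1-S4)",
    "saccade_amplitude_mm": "Mean saccade amplitude (S1-S4) (mm)",
}


def build_report(participants: pd.DataFrame,
                 correlations: pd.DataFrame | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Assemble the five study-style tables from per-participant measures.

    ``participants`` has one row per participant with a ``group`` column
    plus whichever measure columns are available (driving, letter, eye,
    descriptive, TLX); eye rows already excluded for poor tracking carry
    NaN in the eye columns and are dropped from that table's counts.
    Returns a dict of DataFrames keyed ``descriptives``, ``driving``,
    ``letters``, ``eye_scanning``, ``correlations``.
    """
    out: dict[str, pd.DataFrame] = {}
    desc_measures = {
        c: c for c in ("age", "md_od", "md_os", "ivf_loss_pct", "tlx_total_pct")
        if c in participants
    }
    out["descriptives"] = _compare_rows(participants, desc_measures)
    out["driving"] = _compare_rows(
        participants, {k: v for k, v in DRIVING_MEASURES.items()
                       if k in participants})
    out["letters"] = _compare_rows(
        participants, {k: v for k, v in LETTER_MEASURES.items()
                       if k in participants})
    eye_cols = [k for k in EYE_MEASURES if k in participants]
    eye_df = participants
    if "eye_excluded" in participants:
        eye_df = participants[~participants.eye_excluded.astype(bool)]
    out["eye_scanning"] = _compare_rows(
        eye_df, {k: EYE_MEASURES[k] for k in eye_cols})
    out["correlations"] = (correlations if correlations is not None
                           else pd.DataFrame())
    return out
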