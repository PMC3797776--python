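"""24-2 perimetry grid, integrated visual field, and sensitivity-loss summaries.

A 24-2 automated-perimetry field tests 54 locations per eye on a
6°-spaced grid offset 3° from the meridians, two of which fall on the
physiological blind spot (15° temporal, ±3°).  The two monocular fields
are merged into an *integrated visual field* (IVF) by taking, at each of
52 visual-space locations around fixation, the best (maximum) monocular
sensitivity.  Visual-field damage is summarised per quadrant as the
percentage of that quadrant's 13 points whose sensitivity falls below a
25 dB threshold.

Coordinate convention: visual space as seen by the participant,
positive x = right, positive y = up, degrees.  OS (left-eye) grids are
the x-mirror of OD (right-eye) grids; locations are matched between
eyes in visual space.  The IVF keeps the 52 locations with |x| ≤ 21°:
at the four blind-spot-mirrored points (±15°, ±3°) only the fellow eye
sees, and its value is used; the nasal 27° columns, seen by one eye
only and outside the fellow eye's grid, are not part of the IVF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VisualField",
    "IntegratedField",
    "build_grid_24_2",
    "integrate",
    "quadrant_loss",
    "better_worse_eye",
    "QUADRANTS",
    "LOSS_THRESHOLD_DB",
]

LOSS_THRESHOLD_DB = 25.0
QUADRANTS = ("UL", "UR", "LL", "LR")


def build_grid_24_2(eye: str) -> pd.DataFrame:
    """Locations of the 24-2 test pattern for one eye.

    Returns a DataFrame with columns ``x_deg``, ``y_deg``, ``blind_spot``
    (54 rows, 2 flagged).  Rows at y = ±3° extend one extra 6° step to
    27° on the nasal side (left in visual space for OD, right for OS);
    the blind-spot pair sits at 15° temporal, y = ±3°.
    """
    if eye not in ("OD", "OS"):
        raise ValueError(f"eye must be 'OD' or 'OS', got {eye!r}")
    rows: list[tuple[float, float]] = []
    half_widths = {21: 9, 15: 15, 9: 21, 3: 21}
    for y_abs, x_max in half_widths.items():
        for sign in (1, -1):
            y = sign * y_abs
            xs = list(np.arange(-x_max, x_max + 1, 6.0))
            if y_abs == 3:
                xs.append(-27.0)  # nasal extension in the OD frame
            for x in sorted(xs):
                rows.append((x, y))
    grid = pd.DataFrame(rows, columns=["x_deg", "y_deg"])
    blind_x = 15.0  # temporal in the OD frame
    grid["blind_spot"] = (grid.x_deg == blind_x) & (grid.y_deg.abs() == 3)
    if eye == "OS":
        grid["x_deg"] = -grid["x_deg"]
    return grid.sort_values(["y_deg", "x_deg"], ignore_index=True)


@dataclass
class VisualField:
    """One eye's 24-2 field: locations, sensitivities, and mean deviation."""

    eye: str
    locations: pd.DataFrame  # x_deg, y_deg, blind_spot
    sensitivity_db: np.ndarray
    md_db: float | None = None

    def __post_init__(self) -> None:
        self.sensitivity_db = np.asarray(self.sensitivity_db, dtype=float)
        if len(self.sensitivity_db) != len(self.locations):
            raise ValueError("sensitivity length must match locations")
        if np.any(self.sensitivity_db < 0):
            raise ValueError("sensitivities must be non-negative")
        expected = build_grid_24_2(self.eye)[["x_deg", "y_deg"]]
        got = self.locations[["x_deg", "y_deg"]].reset_index(drop=True)
        if not np.allclose(
            got.sort_values(["y_deg", "x_deg"]).to_numpy(),
            expected.sort_values(["y_deg", "x_deg"]).to_numpy(),
        ):
            raise ValueError(f"locations do not follow the 24-2 pattern for {self.eye}")

    @classmethod
    def from_sensitivities(cls, eye: str, sensitivity_db: np.ndarray,
                           md_db: float | None = None) -> "VisualField":
        """Build on the standard grid (sensitivities in grid row order)."""
        return cls(eye, build_grid_24_2(eye), sensitivity_db, md_db)

    def to_frame(self) -> pd.DataFrame:
        out = self.locations.copy()
        out.insert(0, "eye", self.eye)
        out["sensitivity_db"] = self.sensitivity_db
        return out


@dataclass
class IntegratedField:
    """Binocular field estimate: best monocular sensitivity at 52 locations."""

    locations: pd.DataFrame  # x_deg, y_deg, sorted by (y, x)
    sensitivity_db: np.ndarray
    quadrant_loss_pct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.locations) != 52:
            raise ValueError("an integrated field has exactly 52 locations")

    def to_frame(self) -> pd.DataFrame:
        out = self.locations.copy()
        out["sensitivity_db"] = self.sensitivity_db
        return out


def _ivf_location_mask(grid: pd.DataFrame) -> pd.Series:
    return grid.x_deg.abs() <= 21.0


def integrate(od: VisualField, os_: VisualField) -> IntegratedField:
    """Merge OD and OS into the integrated visual field.

    At each of the 52 common visual-space locations the IVF sensitivity
    is the maximum over the eyes that see it; each eye's blind-spot
    locations are covered by the fellow eye alone.
    """
    if od.eye != "OD" or os_.eye != "OS":
        raise ValueError("integrate expects (OD, OS) in that order")

    def seeing(vf: VisualField) -> pd.DataFrame:
        f = vf.locations.copy()
        f["sens"] = vf.sensitivity_db
        f = f[~f.blind_spot & _ivf_location_mask(f)]
        return f.set_index(["y_deg", "x_deg"]).sens

    merged = pd.concat([seeing(od), seeing(os_)]).groupby(level=[0, 1]).max()
    locs = merged.index.to_frame(index=False)[["x_deg", "y_deg"]]
    locs = locs.sort_values(["y_deg", "x_deg"], ignore_index=True)
    sens = merged.reindex(
        pd.MultiIndex.from_frame(locs[["y_deg", "x_deg"]])).to_numpy()
    ivf = IntegratedField(locations=locs, sensitivity_db=sens)
    ivf.quadrant_loss_pct = quadrant_loss(ivf)
    return ivf


def quadrant_loss(fld: IntegratedField | VisualField,
                  threshold_db: float = LOSS_THRESHOLD_DB) -> dict[str, float]:
    """Percentage of points below ``threshold_db`` per visual-field quadrant.

    For an integrated field the denominator is 13 points per quadrant;
    for a monocular field it is that eye's non-blind-spot count in the
    quadrant.  The threshold is strict (a point at exactly 25 dB is not
    counted as depressed).
    """
    locs = fld.locations
    sens = np.asarray(fld.sensitivity_db, dtype=float)
    keep = (~locs.blind_spot.to_numpy() if "blind_spot" in locs else
            np.ones(len(locs), dtype=bool))
    x = locs.x_deg.to_numpy()[keep]
    y = locs.y_deg.to_numpy()[keep]
    s = sens[keep]
    out: dict[str, float] = {}
    for name, (xs, ys) in {
        "UL": (-1, 1), "UR": (1, 1), "LL": (-1, -1), "LR": (1, -1),
    }.items():
        in_q = (np.sign(x) == xs) & (np.sign(y) == ys)
        n = int(in_q.sum())
        out[name] = 100.0 * float((s[in_q] < threshold_db).sum()) / n
    return out


def better_worse_eye(od: VisualField, os_: VisualField
                     ) -> tuple[VisualField, VisualField]:
    """Split the two eyes by mean deviation: (better, worse).

    The better eye is the one with the higher (less negative) MD; on an
    exact tie, OD is taken as the better eye.
    """
    if od.md_db is None or os_.md_db is None:
        raise ValueError("both eyes need a mean deviation to rank them")
    return (od, os_) if od.md_db >= os_.md_db else (os_, od)
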