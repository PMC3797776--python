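"""CSV/JSON serialisation of participant data.

One directory per participant: trace_S{1..4}.csv, gaze_S{1..4}.csv,
events_S{2,4}.csv, vf_od.csv / vf_os.csv (with MD in a sidecar JSON),
tlx.csv and profile.json; plus a cohort-level manifest.json.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_sim import (EventLog, ParticipantProfile, ParticipantRecord,
                         SESSIONS)
from .course import LetterEvent
from .driving_metrics import SessionTrace
from .gaze_metrics import GazeStream
from .stats_report import TLX_ITEMS
from .visual_field import VisualField, build_grid_24_2

__all__ = [
    "write_participant", "read_participant",
    "write_cohort", "read_cohort",
    "write_trace", "read_trace",
    "write_gaze", "read_gaze",
    "write_events", "read_events",
    "write_visual_field", "read_visual_field",
]


def write_trace(trace: SessionTrace, path: Path) -> None:
    pd.DataFrame({"t": trace.t, "s_m": trace.s_m, "y_m": trace.y_m,
                  "steer_deg": trace.steer_deg}).to_csv(path, index=False)


def read_trace(path: Path, session_id: str) -> SessionTrace:
    df = pd.read_csv(path)
    return SessionTrace(session_id, df.t.to_numpy(), df.s_m.to_numpy(),
                        df.y_m.to_numpy(), df.steer_deg.to_numpy())


def write_gaze(gaze: GazeStream, path: Path) -> None:
    pd.DataFrame({"t_s": gaze.t, "x_mm": gaze.x_mm, "y_mm": gaze.y_mm,
                  "valid": gaze.valid.astype(int)}).to_csv(path, index=False)


def read_gaze(path: Path) -> GazeStream:
    df = pd.read_csv(path)
    return GazeStream(df.t_s.to_numpy(), df.x_mm.to_numpy(),
                      df.y_mm.to_numpy(), df.valid.to_numpy().astype(bool))


def write_events(log: EventLog, path: Path) -> None:
    rows = [
        {"kind": "letter", "letter_id": ev.letter_id, "onset_s": ev.onset_s,
         "offset_s": ev.offset_s, "x_mm": ev.x_mm, "y_mm": ev.y_mm}
        for ev in log.letters
    ] + [
        {"kind": "voice", "letter_id": "", "onset_s": t, "offset_s": "",
         "x_mm": "", "y_mm": ""}
        for t in log.voice_events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events(path: Path) -> EventLog:
    df = pd.read_csv(path)
    letters = [
        LetterEvent(int(r.letter_id), float(r.onset_s), float(r.offset_s),
                    float(r.x_mm), float(r.y_mm))
        for r in df[df.kind == "letter"].itertuples()
    ]
    voices = [float(r.onset_s) for r in df[df.kind == "voice"].itertuples()]
    return EventLog(letters=letters, voice_events=sorted(voices))


def write_visual_field(vf: VisualField, path: Path) -> None:
    vf.to_frame().to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"eye": vf.eye, "md_db": vf.md_db}))


def read_visual_field(path: Path) -> VisualField:
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    eye = meta["eye"]
    grid = build_grid_24_2(eye)
    df = df.set_index(["y_deg", "x_deg"]).reindex(
        pd.MultiIndex.from_frame(grid[["y_deg", "x_deg"]]))
    return VisualField(eye, grid, df.sensitivity_db.to_numpy(),
                       md_db=meta["md_db"])


def write_participant(rec: ParticipantRecord, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "profile.json").write_text(
        json.dumps(dataclasses.asdict(rec.profile), indent=2))
    if rec.vf_od is not None:
        write_visual_field(rec.vf_od, outdir / "vf_od.csv")
        write_visual_field(rec.vf_os, outdir / "vf_os.csv")
    for sid, tr in rec.traces.items():
        write_trace(tr, outdir / f"trace_{sid}.csv")
    for sid, g in rec.gaze.items():
        write_gaze(g, outdir / f"gaze_{sid}.csv")
    for sid, log in rec.events.items():
        write_events(log, outdir / f"events_{sid}.csv")
    if rec.tlx:
        pd.DataFrame(
            [{"session": sid, **dict(zip(TLX_ITEMS, items))}
             for sid, items in rec.tlx.items()]
        ).to_csv(outdir / "tlx.csv", index=False)


def read_participant(pdir: Path) -> ParticipantRecord:
    pdir = Path(pdir)
    prof = json.loads((pdir / "profile.json").read_text())
    prof["eye_point_mm"] = tuple(prof["eye_point_mm"])
    rec = ParticipantRecord(profile=ParticipantProfile(**prof))
    if (pdir / "vf_od.csv").exists():
        rec.vf_od = read_visual_field(pdir / "vf_od.csv")
        rec.vf_os = read_visual_field(pdir / "vf_os.csv")
        from .visual_field import integrate
        rec.ivf = integrate(rec.vf_od, rec.vf_os)
    for sid in SESSIONS:
        if (pdir / f"trace_{sid}.csv").exists():
            rec.traces[sid] = read_trace(pdir / f"trace_{sid}.csv", sid)
        if (pdir / f"gaze_{sid}.csv").exists():
            rec.gaze[sid] = read_gaze(pdir / f"gaze_{sid}.csv")
        if (pdir / f"events_{sid}.csv").exists():
            rec.events[sid] = read_events(pdir / f"events_{sid}.csv")
    if (pdir / "tlx.csv").exists():
        df = pd.read_csv(pdir / "tlx.csv")
        for r in df.itertuples():
            rec.tlx[r.session] = np.array([getattr(r, k) for k in TLX_ITEMS],
                                          dtype=float)
    return rec


def write_cohort(records: list[ParticipantRecord], outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = []
    for rec in records:
        write_participant(rec, outdir / rec.profile.id)
        ids.append({"id": rec.profile.id, "group": rec.profile.group,
                    "scotoma_pattern": rec.profile.scotoma_pattern})
    (outdir / "manifest.json").write_text(json.dumps(
        {"participants": ids}, indent=2))


def read_cohort(cdir: Path) -> list[ParticipantRecord]:
    cdir = Path(cdir)
    manifest = json.loads((cdir / "manifest.json").read_text())
    return [read_participant(cdir / p["id"])
            for p in manifest["participants"]]
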