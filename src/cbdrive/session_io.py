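"""On-disk session format: one directory per participant.

The layout is a plain-text invention of this package (the study's raw logger
schema is not public): columnar streams in CSV, structured metadata in JSON.

    <participant>/
        gaze.csv     t,gx,gy,gz,hx,hy,hz,valid
        driving.csv  t,speed_kmh,brake
        presses.csv  t,side
        events.json  list of change-event records
        aois.json    list of AOI records with track arrays
        meta.json    participant_id, group, segment_bounds, seed, version

Floats round-trip exactly (shortest-repr CSV serialisation); ``read_session``
re-validates every invariant on load and raises :class:`SessionFormatError`
naming the missing file or :class:`ValidationError` naming the offending
record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AOI,
    ButtonPress,
    ChangeEvent,
    DrivingStream,
    GazeStream,
    SessionFormatError,
    SessionLog,
)

__all__ = ["read_session", "write_session", "read_cohort", "write_cohort"]

_FILES = ("gaze.csv", "driving.csv", "presses.csv", "events.json", "aois.json", "meta.json")


def write_session(session: SessionLog, path: str | Path) -> Path:
    """Write a validated session to ``path`` (created if needed)."""
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    g = session.gaze
    pd.DataFrame(
        {
            "t": g.t,
            "gx": g.gaze_dir[:, 0], "gy": g.gaze_dir[:, 1], "gz": g.gaze_dir[:, 2],
            "hx": g.head_pos[:, 0], "hy": g.head_pos[:, 1], "hz": g.head_pos[:, 2],
            "valid": g.valid.astype(int),
        }
    ).to_csv(path / "gaze.csv", index=False)

    d = session.driving
    pd.DataFrame(
        {"t": d.t, "speed_kmh": d.speed_kmh, "brake": d.brake.astype(int)}
    ).to_csv(path / "driving.csv", index=False)

    pd.DataFrame(
        {"t": [p.t for p in session.presses], "side": [p.side for p in session.presses]}
    ).to_csv(path / "presses.csv", index=False)

    events = [
        {
            "change_id": e.change_id,
            "pair_id": e.pair_id,
            "change_type": e.change_type,
            "complexity": e.complexity,
            "trigger_t": e.trigger_t,
            "aoi_id": e.aoi_id,
            "gap_s": e.gap_s,
            "encounter_index": e.encounter_index,
        }
        for e in session.events
    ]
    (path / "events.json").write_text(json.dumps(events, indent=1))

    aois = [
        {
            "aoi_id": a.aoi_id,
            "kind": a.kind,
            "radius": a.radius,
            "track_t": a.track_t.tolist(),
            "track_center": a.track_center.tolist(),
        }
        for a in session.aois.values()
    ]
    (path / "aois.json").write_text(json.dumps(aois, indent=1))

    meta = {
        "participant_id": session.participant_id,
        "group": session.group,
        "segment_bounds": {k: list(v) for k, v in session.segment_bounds.items()},
        **session.meta,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_session(path: str | Path) -> SessionLog:
    """Read and fully validate one session directory."""
    path = Path(path)
    for name in _FILES:
        if not (path / name).is_file():
            raise SessionFormatError(f"session {path}: missing file {name}")

    gz = pd.read_csv(path / "gaze.csv")
    gaze = GazeStream(
        t=gz["t"].to_numpy(),
        gaze_dir=gz[["gx", "gy", "gz"]].to_numpy(),
        head_pos=gz[["hx", "hy", "hz"]].to_numpy(),
        valid=gz["valid"].to_numpy().astype(bool),
    )

    dv = pd.read_csv(path / "driving.csv")
    driving = DrivingStream(
        t=dv["t"].to_numpy(),
        speed_kmh=dv["speed_kmh"].to_numpy(),
        brake=dv["brake"].to_numpy().astype(bool),
    )

    pr = pd.read_csv(path / "presses.csv")
    presses = [ButtonPress(t=float(t), side=str(s)) for t, s in zip(pr["t"], pr["side"])]

    events = [ChangeEvent(**rec) for rec in json.loads((path / "events.json").read_text())]

    aois = {}
    for rec in json.loads((path / "aois.json").read_text()):
        aois[rec["aoi_id"]] = AOI(
            aoi_id=rec["aoi_id"],
            kind=rec["kind"],
            track_t=np.asarray(rec["track_t"]),
            track_center=np.asarray(rec["track_center"]),
            radius=rec["radius"],
        )

    meta = json.loads((path / "meta.json").read_text())
    session = SessionLog(
        participant_id=meta.pop("participant_id"),
        group=meta.pop("group"),
        gaze=gaze,
        driving=driving,
        presses=presses,
        events=events,
        aois=aois,
        segment_bounds={k: (float(a), float(b)) for k, (a, b) in meta.pop("segment_bounds").items()},
        meta=meta,
    )
    session.validate()
    return session


def write_cohort(sessions, path: str | Path) -> Path:
    path = Path(path)
    for s in sessions:
        write_session(s, path / s.participant_id)
    return path


def read_cohort(path: str | Path) -> list[SessionLog]:
    path = Path(path)
    dirs = sorted(p for p in path.iterdir() if p.is_dir() and (p / "meta.json").is_file())
    if not dirs:
        raise SessionFormatError(f"cohort {path}: no session directories found")
    return [read_session(p) for p in dirs]
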