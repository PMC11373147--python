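"""Session CSV dialects, study manifests and config files.

One session is three CSVs sharing a ``{participant}_{condition}`` suffix:

* ``gaze_{p}_{c}.csv`` — t, dir_x, dir_y, dir_z, pd_left_mm, pd_right_mm, valid
* ``eeg_{p}_{c}.csv``  — t plus one column per electrode (uV)
* ``stick_{p}_{c}.csv`` — t, delta_deg

``manifest.json`` maps each session to its participant, condition and
difficulty and records the stick displacement limit.  Study configuration
(design + effect profile) round-trips through a flat YAML mapping.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inceptor import StickSeries
from .ocular import GazeSeries
from .synthetic import EffectProfile, SessionData, StudyDesign

__all__ = [
    "write_session",
    "write_study",
    "read_gaze_csv",
    "read_eeg_csv",
    "read_stick_csv",
    "load_study",
    "load_config",
    "save_config",
]


def write_session(session: SessionData, outdir: str | Path) -> dict:
    """Write one session's three CSVs; returns its manifest entry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p, c = session.participant, session.condition
    g = session.gaze
    gaze_df = pd.DataFrame(
        {
            "t": g.t,
            "dir_x": g.dir[:, 0],
            "dir_y": g.dir[:, 1],
            "dir_z": g.dir[:, 2],
            "pd_left_mm": g.pd_left,
            "pd_right_mm": g.pd_right,
            "valid": g.valid.astype(int),
        }
    )
    gaze_df.to_csv(outdir / f"gaze_{p}_{c}.csv", index=False)
    session.eeg.to_csv(outdir / f"eeg_{p}_{c}.csv", index=False)
    stick_df = pd.DataFrame({"t": session.stick.t, "delta_deg": session.stick.delta})
    stick_df.to_csv(outdir / f"stick_{p}_{c}.csv", index=False)
    return {
        "participant": p,
        "condition": c,
        "difficulty": session.difficulty,
        "delta_max": session.stick.delta_max,
        "gaze": f"gaze_{p}_{c}.csv",
        "eeg": f"eeg_{p}_{c}.csv",
        "stick": f"stick_{p}_{c}.csv",
    }


def write_study(sessions: list[SessionData], outdir: str | Path) -> Path:
    """Write every session plus ``manifest.json``; returns the manifest path."""
    outdir = Path(outdir)
    entries = [write_session(s, outdir) for s in sessions]
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({"sessions": entries}, indent=2))
    return manifest


def read_gaze_csv(path: str | Path) -> GazeSeries:
    df = pd.read_csv(path)
    required = {"t", "dir_x", "dir_y", "dir_z", "pd_left_mm", "pd_right_mm", "valid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing gaze columns {sorted(missing)}")
    return GazeSeries(
        t=df["t"].to_numpy(float),
        dir=df[["dir_x", "dir_y", "dir_z"]].to_numpy(float),
        pd_left=df["pd_left_mm"].to_numpy(float),
        pd_right=df["pd_right_mm"].to_numpy(float),
        valid=df["valid"].to_numpy(bool),
    )


def read_eeg_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise ValueError(f"{path}: EEG CSV needs a 't' column")
    return df


def read_stick_csv(path: str | Path, delta_max: float) -> StickSeries:
    df = pd.read_csv(path)
    missing = {"t", "delta_deg"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing stick columns {sorted(missing)}")
    return StickSeries(
        t=df["t"].to_numpy(float),
        delta=df["delta_deg"].to_numpy(float),
        delta_max=delta_max,
    )


def load_study(indir: str | Path) -> list[SessionData]:
    """Rehydrate a written study from its manifest."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    sessions = []
    for entry in manifest["sessions"]:
        sessions.append(
            SessionData(
                participant=int(entry["participant"]),
                condition=int(entry["condition"]),
                difficulty=float(entry["difficulty"]),
                gaze=read_gaze_csv(indir / entry["gaze"]),
                eeg=read_eeg_csv(indir / entry["eeg"]),
                stick=read_stick_csv(indir / entry["stick"], entry["delta_max"]),
                planted={},
            )
        )
    return sessions


def load_config(path: str | Path) -> tuple[StudyDesign, EffectProfile]:
    """Read a flat YAML mapping into (StudyDesign, EffectProfile)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    design_fields = {f.name for f in dataclasses.fields(StudyDesign)}
    effect_fields = {f.name for f in dataclasses.fields(EffectProfile)}
    unknown = set(raw) - design_fields - effect_fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    dk = {k: v for k, v in raw.items() if k in design_fields}
    if "condition_difficulties" in dk:
        dk["condition_difficulties"] = tuple(dk["condition_difficulties"])
    ek = {k: v for k, v in raw.items() if k in effect_fields}
    return StudyDesign(**dk), EffectProfile(**ek)


def save_config(
    design: StudyDesign, effects: EffectProfile, path: str | Path
) -> None:
    out = {**dataclasses.asdict(design), **dataclasses.asdict(effects)}
    out["condition_difficulties"] = list(out["condition_difficulties"])
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")
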