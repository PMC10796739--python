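"""File formats: session CSVs, label sidecars, cohort manifests, windows.

A session is stored as ``<subject>_<side>.csv`` with columns ``t,ax,ay,az``
(seconds, m/s^2) plus a sidecar ``<subject>_<side>_labels.csv`` with
columns ``start_s,end_s,task_type,role`` (role: active/passive).  The
cohort manifest is a JSON list of subject records.  Kinematics are CSV
``t,ax,ay,az,vx,vy,vz`` at 25 Hz; windows are stored as a self-describing
NumPy ``.npz`` container with a window manifest CSV alongside.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import KinematicsPair
from .segmentation import WindowSet
from .synthcohort import Session, SubjectSpec


def _segments_from_samples(task_type: np.ndarray, active: np.ndarray, fs: float) -> pd.DataFrame:
    change = np.flatnonzero(
        (task_type[1:] != task_type[:-1]) | (active[1:] != active[:-1])
    ) + 1
    bounds = np.concatenate([[0], change, [len(task_type)]])
    rows = [
        {
            "start_s": bounds[i] / fs,
            "end_s": bounds[i + 1] / fs,
            "task_type": str(task_type[bounds[i]]),
            "role": "active" if active[bounds[i]] else "passive",
        }
        for i in range(len(bounds) - 1)
    ]
    return pd.DataFrame(rows)


def write_session(directory: str | Path, session: Session) -> None:
    directory = Path(directory)
    stem = f"{session.subject_id}_{session.side}"
    n = len(session.acc)
    t = np.arange(n) / session.fs
    pd.DataFrame({
        "t": t, "ax": session.acc[:, 0], "ay": session.acc[:, 1], "az": session.acc[:, 2],
    }).to_csv(directory / f"{stem}.csv", index=False, float_format="%.6f")
    _segments_from_samples(session.task_type, session.active, session.fs).to_csv(
        directory / f"{stem}_labels.csv", index=False
    )


def read_session(directory: str | Path, subject_id: str, side: str) -> Session:
    directory = Path(directory)
    stem = f"{subject_id}_{side}"
    df = pd.read_csv(directory / f"{stem}.csv")
    fs = 1.0 / np.median(np.diff(df["t"].to_numpy()))
    fs = float(round(fs))
    acc = df[["ax", "ay", "az"]].to_numpy()
    labels = pd.read_csv(directory / f"{stem}_labels.csv")
    task = np.empty(len(acc), dtype=object)
    active = np.zeros(len(acc), dtype=bool)
    for row in labels.itertuples():
        lo = int(round(row.start_s * fs))
        hi = int(round(row.end_s * fs))
        task[lo:hi] = row.task_type
        active[lo:hi] = row.role == "active"
    return Session(subject_id=subject_id, side=side, fs=fs, acc=acc,
                   task_type=task, active=active)


def write_cohort(
    directory: str | Path,
    subjects: Sequence[SubjectSpec],
    sessions: Mapping[tuple[str, str], Session],
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = [
        {
            "subject_id": s.subject_id, "group": s.group,
            "impairment": s.impairment, "fma": s.fma,
            "affected_side": s.affected_side,
        }
        for s in subjects
    ]
    (directory / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    for session in sessions.values():
        write_session(directory, session)


def read_cohort(
    directory: str | Path,
) -> tuple[list[SubjectSpec], dict[tuple[str, str], Session]]:
    directory = Path(directory)
    manifest = json.loads((directory / "cohort_manifest.json").read_text())
    subjects = [SubjectSpec(**rec) for rec in manifest]
    sessions = {}
    for s in subjects:
        for side in ("left", "right"):
            if (directory / f"{s.subject_id}_{side}.csv").exists():
                sessions[(s.subject_id, side)] = read_session(directory, s.subject_id, side)
    return subjects, sessions


def write_kinematics(path: str | Path, kin: KinematicsPair) -> None:
    t = np.arange(len(kin.acc)) / kin.fs
    pd.DataFrame({
        "t": t,
        "ax": kin.acc[:, 0], "ay": kin.acc[:, 1], "az": kin.acc[:, 2],
        "vx": kin.vel[:, 0], "vy": kin.vel[:, 1], "vz": kin.vel[:, 2],
    }).to_csv(path, index=False, float_format="%.6f")


def read_kinematics(path: str | Path) -> KinematicsPair:
    df = pd.read_csv(path)
    fs = float(round(1.0 / np.median(np.diff(df["t"].to_numpy()))))
    return KinematicsPair(
        acc=df[["ax", "ay", "az"]].to_numpy(),
        vel=df[["vx", "vy", "vz"]].to_numpy(),
        fs=fs,
    )


def write_windows(path: str | Path, window_sets: Sequence[WindowSet]) -> None:
    """Self-describing .npz of all window sets plus a manifest CSV."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    manifest_rows = []
    for i, w in enumerate(window_sets):
        arrays[f"data_{i}"] = w.data
        arrays[f"start_{i}"] = w.start
        arrays[f"gdm_{i}"] = w.gdm_label
        arrays[f"context_{i}"] = w.task_context.astype(str)
        manifest_rows.append({
            "index": i, "subject_id": w.subject_id, "side": w.side,
            "fs": w.fs, "hop": w.hop, "n_samples": w.n_samples,
            "n_windows": len(w),
        })
    np.savez_compressed(path, n_sets=np.array(len(window_sets)), **arrays)
    pd.DataFrame(manifest_rows).to_csv(path.with_suffix(".manifest.csv"), index=False)


def read_windows(path: str | Path) -> list[WindowSet]:
    path = Path(path)
    npz = np.load(path, allow_pickle=False)
    manifest = pd.read_csv(path.with_suffix(".manifest.csv"))
    sets = []
    for row in manifest.itertuples():
        i = row.index
        sets.append(WindowSet(
            subject_id=row.subject_id, side=row.side, fs=row.fs,
            data=npz[f"data_{i}"], start=npz[f"start_{i}"],
            gdm_label=npz[f"gdm_{i}"],
            task_context=npz[f"context_{i}"].astype(object),
            hop=int(row.hop), n_samples=int(row.n_samples),
        ))
    return sets
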