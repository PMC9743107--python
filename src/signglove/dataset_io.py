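"""Reading and writing the folder-per-subject, folder-per-gesture dataset
layout, plus the package's own CSV/PNG/JSON artifact formats.

One trial is one delimited text file of 18 named columns (comma or tab),
one row per 10 ms sample.  The reader is schema-driven: a mapping from the
canonical channel names to file column names can be supplied (as a dict or a
YAML file) for deposits whose column order differs from the default.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .recording import DEFAULT_COLUMNS, DEFAULT_FS, DEFAULT_WINDOW, GestureRecording
from .spatial_projection import ProjectionImageSet

logger = logging.getLogger("signglove")

__all__ = [
    "DatasetManifest",
    "default_schema",
    "read_recording",
    "write_recording",
    "write_dataset",
    "read_dataset",
    "scan_dataset",
    "write_projection_images",
]


def default_schema() -> dict[str, str]:
    """Canonical channel name -> column name (identity by default)."""
    return {name: name for name in DEFAULT_COLUMNS}


def load_schema(path) -> dict[str, str]:
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    missing = set(DEFAULT_COLUMNS) - set(schema)
    if missing:
        raise ValueError(f"schema missing channels: {sorted(missing)}")
    return schema


def _coerce_window(mat: np.ndarray, target: int, path) -> np.ndarray:
    n = mat.shape[0]
    if n == target:
        return mat
    if n > target:
        warnings.warn(
            f"{path}: {n} samples truncated to {target} (tail dropped)",
            stacklevel=3,
        )
        return mat[:target]
    warnings.warn(
        f"{path}: {n} samples padded to {target} by edge replication",
        stacklevel=3,
    )
    pad = np.repeat(mat[-1:], target - n, axis=0)
    return np.vstack([mat, pad])


def read_recording(
    path,
    subject_id: str,
    gesture_label: str,
    kind: str,
    schema: dict[str, str] | None = None,
    fs: float = DEFAULT_FS,
    target_len: int = DEFAULT_WINDOW,
) -> GestureRecording:
    """Parse one trial file into a validated recording.

    Accepts comma- or tab-delimited text.  Missing channels raise naming the
    channel; non-numeric cells raise with the row index.  Windows shorter
    than ``target_len`` are padded by edge replication, longer ones truncated.
    """
    path = Path(path)
    schema = schema or default_schema()
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = []
    for canonical in DEFAULT_COLUMNS:
        col = schema.get(canonical, canonical)
        if col not in df.columns:
            raise ValueError(f"{path}: missing channel column {col!r} ({canonical})")
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at row {row}"
            )
        if series.isna().any():
            row = int(np.flatnonzero(series.isna())[0])
            raise ValueError(f"{path}: missing value in column {col!r} at row {row}")
        cols.append(series.to_numpy(dtype=float))
    mat = np.column_stack(cols)
    mat = _coerce_window(mat, target_len, path)
    return GestureRecording.from_matrix(
        mat, subject_id=subject_id, gesture_label=gesture_label, kind=kind, fs=fs
    )


def write_recording(rec: GestureRecording, path) -> None:
    """One CSV per trial, 18 named columns, full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rec.to_matrix(), columns=DEFAULT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def write_dataset(recordings, root) -> None:
    """subject/gesture/trial_XX.csv layout plus a gesture-kind map."""
    root = Path(root)
    kinds: dict[str, str] = {}
    counters: dict[tuple[str, str], int] = {}
    for rec in recordings:
        kinds[rec.gesture_label] = rec.kind
        key = (rec.subject_id, rec.gesture_label)
        trial = rec.meta.get("trial", counters.get(key, 0))
        counters[key] = counters.get(key, 0) + 1
        out = root / rec.subject_id / rec.gesture_label / f"trial_{trial:02d}.csv"
        write_recording(rec, out)
    with open(root / "gesture_kinds.json", "w") as fh:
        json.dump(kinds, fh, indent=2, sort_keys=True)
    logger.info("wrote %d recordings under %s", len(list(recordings)), root)


@dataclass
class DatasetManifest:
    """Inventory of a dataset tree: who, what, how many, and any surprises."""

    root: str
    subjects: list[str]
    gestures: dict[str, str]  # gesture -> kind
    trial_counts: dict[str, int]  # "subject/gesture" -> count
    ac_noise_sessions: list[str] = field(default_factory=list)
    anomalies: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "DatasetManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def scan_dataset(root, ac_noise_file=None) -> DatasetManifest:
    """Walk a subject/gesture/trial tree; report counts, never drop files.

    ``ac_noise_file`` optionally points to a text file listing
    ``subject/gesture`` sessions contaminated by mains noise (one per line),
    as identified in a deposit's supplementary notes.
    """
    root = Path(root)
    if not root.is_dir() or not any(root.iterdir()):
        raise ValueError(f"dataset root {root} is empty or missing")
    kinds_file = root / "gesture_kinds.json"
    gestures: dict[str, str] = {}
    if kinds_file.exists():
        gestures = json.loads(kinds_file.read_text())
    subjects = []
    trial_counts: dict[str, int] = {}
    anomalies: list[str] = []
    for entry in sorted(root.iterdir()):
        if entry.name == "gesture_kinds.json":
            continue
        if not entry.is_dir():
            anomalies.append(f"unexpected file: {entry.name}")
            continue
        subjects.append(entry.name)
        for gdir in sorted(entry.iterdir()):
            if not gdir.is_dir():
                anomalies.append(f"unexpected file: {gdir.relative_to(root)}")
                continue
            gestures.setdefault(gdir.name, "unknown")
            count = 0
            for trial in sorted(gdir.iterdir()):
                if trial.suffix.lower() in (".csv", ".tsv", ".txt"):
                    count += 1
                else:
                    anomalies.append(f"unexpected file: {trial.relative_to(root)}")
            trial_counts[f"{entry.name}/{gdir.name}"] = count
    ac_sessions = []
    if ac_noise_file:
        ac_sessions = [
            line.strip()
            for line in Path(ac_noise_file).read_text().splitlines()
            if line.strip()
        ]
    return DatasetManifest(
        root=str(root),
        subjects=subjects,
        gestures=gestures,
        trial_counts=trial_counts,
        ac_noise_sessions=ac_sessions,
        anomalies=anomalies,
    )


def read_dataset(
    root, schema: dict[str, str] | None = None, manifest: DatasetManifest | None = None
) -> list[GestureRecording]:
    """Load every trial under a dataset tree into recordings."""
    root = Path(root)
    manifest = manifest or scan_dataset(root)
    ac = set(manifest.ac_noise_sessions)
    recordings = []
    for session, count in sorted(manifest.trial_counts.items()):
        subject, gesture = session.split("/", 1)
        kind = manifest.gestures.get(gesture, "unknown")
        gdir = root / subject / gesture
        for trial_file in sorted(gdir.iterdir()):
            if trial_file.suffix.lower() not in (".csv", ".tsv", ".txt"):
                continue
            rec = read_recording(
                trial_file,
                subject_id=subject,
                gesture_label=gesture,
                kind=kind if kind in ("static", "dynamic") else "static",
                schema=schema,
            )
            if session in ac:
                rec.meta["ac_noise"] = True
            recordings.append(rec)
    return recordings


def write_projection_images(image_set: ProjectionImageSet, out_dir, stem: str) -> list[Path]:
    """One 8-bit grayscale PNG per plane: ``<stem>_<plane>.png``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for plane, img in image_set.images.items():
        arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
        path = out_dir / f"{stem}_{plane}.png"
        Image.fromarray(arr, mode="L").save(path)
        paths.append(path)
    return paths
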