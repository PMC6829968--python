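"""File I/O: session CSVs, sidecar metadata, and index/statistics tables.

Session signal files are plain wide-format CSV (header row, UTF-8, ``.``
decimal): an optional leading time/index column followed by one column per
channel named ``"<MUSCLE>_<SIDE>"``.  Subject metadata and trial annotations
live in a YAML sidecar so the signal file stays a standard numeric table.
Per-trial index results are written as TSV.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data import EmgSession, Group, IndexRecord, Motion, SubjectMeta, TrialAnnotation
from .errors import EmgError, FormatError, ValidationError
from .montage import ChannelLabel, Side

__all__ = [
    "read_session",
    "write_session",
    "read_sidecar",
    "write_sidecar",
    "load_session",
    "save_session",
    "write_index_table",
    "read_index_table",
]

_TIME_COLUMNS = {"time", "time_s", "t", "sample", "index"}


def _validate_time_column(values: np.ndarray, name: str, sample_rate: float) -> None:
    """Uniform-spacing check (1 ppm) for an explicit time column; then discarded."""
    if len(values) < 2:
        return
    steps = np.diff(values.astype(float))
    expected = 1.0 if name in {"sample", "index"} else 1.0 / sample_rate
    if not np.allclose(steps, expected, rtol=1e-6, atol=expected * 1e-6):
        raise FormatError(
            f"time column {name!r} is not uniform at sample_rate={sample_rate:g}"
        )


def read_session(
    path: str | Path,
    meta: SubjectMeta,
    annotations: Sequence[TrialAnnotation] = (),
    sample_rate: float = 1000.0,
) -> EmgSession:
    """Read a wide-format session CSV.

    Column names must parse as channel labels; a single leading column named
    ``time``/``t``/``time_s``/``sample``/``index`` is validated against
    ``sample_rate`` and dropped.  Unknown columns and ragged/non-numeric rows
    are format errors.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, header=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    columns = list(frame.columns)
    labels: list[ChannelLabel] = []
    data_cols: list[str] = []
    for i, col in enumerate(columns):
        label = ChannelLabel.try_parse(str(col))
        if label is None:
            if i == 0 and str(col).strip().lower() in _TIME_COLUMNS:
                _validate_time_column(
                    frame[col].to_numpy(), str(col).strip().lower(), sample_rate
                )
                continue
            raise FormatError(f"{path.name}: unknown channel column {col!r}")
        labels.append(label)
        data_cols.append(col)
    if not labels:
        raise FormatError(f"{path.name}: no channel columns found")
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path.name}: duplicate channel columns")
    matrix = np.empty((len(labels), len(frame)), dtype=float)
    for row_idx, (_, col) in enumerate(zip(labels, data_cols)):
        values = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(np.isnan(values))
        if bad.size:
            # +2: header row plus 1-based numbering
            raise FormatError(
                f"{path.name}: non-numeric or missing value in column {col!r}, "
                f"file row {bad[0] + 2}"
            )
        matrix[row_idx] = values
    for ann in annotations:
        if ann.end_sample > matrix.shape[1]:
            raise ValidationError(
                f"annotation [{ann.start_sample}, {ann.end_sample}) exceeds "
                f"session length {matrix.shape[1]}"
            )
    return EmgSession(
        meta=meta,
        sample_rate=sample_rate,
        channels=tuple(labels),
        samples=matrix,
        annotations=tuple(annotations),
    )


def write_session(
    session: EmgSession, path: str | Path, include_time: bool = False
) -> Path:
    """Write the signal matrix as wide CSV with canonical uppercase labels."""
    path = Path(path)
    frame = pd.DataFrame(
        {str(label): session.samples[i] for i, label in enumerate(session.channels)}
    )
    if include_time:
        frame.insert(0, "time_s", np.arange(session.n_samples) / session.sample_rate)
    frame.to_csv(path, index=False, float_format="%.12g")
    return path


def write_sidecar(session: EmgSession, path: str | Path) -> Path:
    """Write the metadata/annotation sidecar (YAML)."""
    meta = session.meta
    doc: dict = {
        "subject_id": meta.subject_id,
        "group": meta.group.value,
        "sample_rate": float(session.sample_rate),
        "trials": [
            {
                "motion": a.motion.value,
                "start_sample": int(a.start_sample),
                "end_sample": int(a.end_sample),
            }
            for a in session.annotations
        ],
    }
    if meta.sias_level is not None:
        doc["sias_level"] = int(meta.sias_level)
    if meta.paretic_side is not None:
        doc["paretic_side"] = meta.paretic_side.value.lower()
    if meta.dominant_side is not None:
        doc["dominant_side"] = meta.dominant_side.value.lower()
    if session.ground_truth is not None:
        doc["ground_truth"] = session.ground_truth
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_sidecar(path: str | Path) -> tuple[SubjectMeta, tuple[TrialAnnotation, ...], float, dict | None]:
    """Read a sidecar; returns (meta, annotations, sample_rate, ground_truth)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: sidecar is not a mapping")
    try:
        meta = SubjectMeta(
            subject_id=str(doc["subject_id"]),
            group=Group(doc["group"]),
            sias_level=doc.get("sias_level"),
            paretic_side=Side(doc["paretic_side"].upper()) if "paretic_side" in doc else None,
            dominant_side=Side(doc["dominant_side"].upper()) if "dominant_side" in doc else None,
        )
        annotations = tuple(
            TrialAnnotation(
                motion=Motion(t["motion"]),
                start_sample=int(t["start_sample"]),
                end_sample=int(t["end_sample"]),
            )
            for t in doc.get("trials", [])
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad sidecar field: {exc}") from exc
    return meta, annotations, float(doc.get("sample_rate", 1000.0)), doc.get("ground_truth")


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".meta.yaml")


def load_session(csv_path: str | Path) -> EmgSession:
    """Read a session CSV together with its ``<stem>.meta.yaml`` sidecar."""
    meta, annotations, rate, truth = read_sidecar(sidecar_path(csv_path))
    session = read_session(csv_path, meta, annotations, sample_rate=rate)
    session.ground_truth = truth
    return session


def save_session(session: EmgSession, csv_path: str | Path, include_time: bool = False) -> Path:
    """Write a session CSV plus its sidecar; returns the CSV path."""
    write_session(session, csv_path, include_time=include_time)
    write_sidecar(session, sidecar_path(csv_path))
    return Path(csv_path)


_INDEX_COLUMNS = ["subject_id", "group", "sias_level", "motion", "trial_index", "esb", "mcs"]


def write_index_table(records: Sequence[IndexRecord], path: str | Path) -> Path:
    """Write per-trial (ESB, MCS) records as TSV; undefined MCS becomes ``NA``."""
    if not records:
        raise EmgError("no index records to write")
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group.value,
            "sias_level": "NA" if r.sias_level is None else int(r.sias_level),
            "motion": r.motion.value,
            "trial_index": r.trial_index,
            "esb": f"{r.esb:.12g}",
            "mcs": "NA" if r.mcs is None else f"{r.mcs:.12g}",
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=_INDEX_COLUMNS)
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_index_table(path: str | Path) -> list[IndexRecord]:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = set(_INDEX_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        sias = row["sias_level"]
        mcs = row["mcs"]
        records.append(
            IndexRecord(
                subject_id=str(row["subject_id"]),
                group=Group(row["group"]),
                sias_level=None if pd.isna(sias) else int(sias),
                motion=Motion(row["motion"]),
                trial_index=int(row["trial_index"]),
                esb=float(row["esb"]),
                mcs=None if (mcs is None or (isinstance(mcs, float) and math.isnan(mcs))) else float(mcs),
            )
        )
    return records
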