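"""CSV readers/writers for every pipeline artifact.

All artifacts are plain CSV with documented headers so intermediate
state stays inspectable.  Readers validate headers and row contents and
reject malformed input with the offending line number; writers are the
inverse, and write-then-read round-trips reproduce the in-memory
objects exactly (floats via full repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from wristhar.classification import ActivityResult, RunResult, WindowDataset
from wristhar.segmentation import WindowInstance
from wristhar.synthetic import DEFAULT_CHANNELS, IMUStream, LabelInterval
from wristhar.window_analysis import WindowSizeFit

STREAM_HEADER = ("t",) + DEFAULT_CHANNELS
LABEL_HEADER = ("subject_id", "activity", "start_index", "end_index", "bout_id")
WINDOW_HEADER = ("subject_id", "start_index", "window_size", "label", "spans_transition")
RUN_HEADER = (
    "activity", "window_size", "fold", "iteration",
    "auc", "accuracy", "n_test_windows", "n_test_positives",
)
ACTIVITY_HEADER = (
    "activity", "activity_type", "window_size", "accuracy", "auc", "num_pos", "pos_pct",
)
FIT_HEADER = (
    "activity", "b0", "b1", "b2", "r2", "adj_r2",
    "effect_size", "local_max_window", "relevant",
)


class FormatError(ValueError):
    """Malformed artifact file."""


def _check_header(df: pd.DataFrame, expected: Sequence[str], path: Path) -> None:
    if list(df.columns)[: len(expected)] != list(expected):
        raise FormatError(
            f"{path}: header mismatch: expected {list(expected)}, got {list(df.columns)}"
        )


def _read_csv(path: Path, expected: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    _check_header(df, expected, path)
    return df


# -- streams ---------------------------------------------------------------

def write_stream(stream: IMUStream, directory: Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{stream.subject_id}.csv"
    t = np.arange(stream.n_samples) / stream.sampling_rate
    df = pd.DataFrame(stream.samples[:, :6], columns=DEFAULT_CHANNELS)
    df.insert(0, "t", t)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_stream(path: Path, sampling_rate: float = 50.0) -> IMUStream:
    path = Path(path)
    df = _read_csv(path, STREAM_HEADER)
    for col in STREAM_HEADER:
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise FormatError(f"{path}: non-numeric cell in column {col}, line {bad[0] + 2}")
    if len(df) > 1:
        dt = np.diff(df["t"].to_numpy())
        sampling_rate = float(round(1.0 / np.median(dt), 6))
    return IMUStream(
        subject_id=path.stem,
        sampling_rate=sampling_rate,
        channels=DEFAULT_CHANNELS,
        samples=df[list(DEFAULT_CHANNELS)].to_numpy(dtype=float),
    )


def read_streams(directory: Path) -> list[IMUStream]:
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"missing stream directory: {directory}")
    return [read_stream(p) for p in sorted(directory.glob("*.csv"))]


# -- label intervals -------------------------------------------------------

def write_labels(labels: Sequence[LabelInterval], path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            (iv.subject_id, iv.activity, iv.start_index, iv.end_index, iv.bout_id)
            for iv in labels
        ],
        columns=list(LABEL_HEADER),
    )
    df.to_csv(path, index=False)
    return path


def read_labels(path: Path) -> list[LabelInterval]:
    path = Path(path)
    df = _read_csv(path, LABEL_HEADER)
    out: list[LabelInterval] = []
    for i, row in df.iterrows():
        line = int(i) + 2
        try:
            start, end = int(row.start_index), int(row.end_index)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-integer index on line {line}") from exc
        if not 0 <= start < end:
            raise FormatError(f"{path}: index violation on line {line}: [{start}, {end})")
        out.append(
            LabelInterval(str(row.subject_id), str(row.activity), start, end, str(row.bout_id))
        )
    _reject_overlaps(out, path)
    return out


def _reject_overlaps(labels: Sequence[LabelInterval], path: Path) -> None:
    by_subject: dict[str, list[LabelInterval]] = {}
    for iv in labels:
        by_subject.setdefault(iv.subject_id, []).append(iv)
    for sid, ivs in by_subject.items():
        ivs = sorted(ivs, key=lambda iv: iv.start_index)
        for a, b in zip(ivs, ivs[1:]):
            if b.start_index < a.end_index:
                raise FormatError(
                    f"{path}: overlapping intervals for subject {sid}: "
                    f"{a.bout_id} and {b.bout_id}"
                )


# -- windows ---------------------------------------------------------------

def write_windows(windows: Sequence[WindowInstance], path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            (w.subject_id, w.start_index, w.window_size, w.label, w.spans_transition)
            for w in windows
        ],
        columns=list(WINDOW_HEADER),
    )
    df.to_csv(path, index=False)
    return path


def read_windows(path: Path) -> list[WindowInstance]:
    df = _read_csv(Path(path), WINDOW_HEADER)
    return [
        WindowInstance(
            str(r.subject_id), int(r.start_index), int(r.window_size),
            str(r.label), bool(r.spans_transition),
        )
        for r in df.itertuples(index=False)
    ]


# -- feature matrices ------------------------------------------------------

def write_features(
    ds: WindowDataset,
    path: Path,
    bands: Sequence[tuple[float, float]],
    sampling_rate: float,
) -> Path:
    """Feature matrix CSV plus a JSON sidecar with the column contract."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(ds.X, columns=list(ds.feature_names))
    df.insert(0, "subject_id", ds.subjects)
    df.insert(1, "label", ds.labels)
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "window_size": ds.window_size,
        "sampling_rate": sampling_rate,
        "bands": [list(b) for b in bands],
        "feature_order": list(ds.feature_names),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_features(path: Path) -> WindowDataset:
    path = Path(path)
    meta_path = path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing feature metadata: {meta_path}")
    meta = json.loads(meta_path.read_text())
    df = _read_csv(path, ("subject_id", "label"))
    names = meta["feature_order"]
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing feature columns {missing[:3]}...")
    return WindowDataset(
        window_size=int(meta["window_size"]),
        X=df[names].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=str),
        subjects=df["subject_id"].to_numpy(dtype=str),
        feature_names=tuple(names),
    )


# -- results ---------------------------------------------------------------

def write_runs(runs: Sequence[RunResult], path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([r.__dict__ for r in runs], columns=list(RUN_HEADER))
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_runs(path: Path) -> list[RunResult]:
    df = _read_csv(Path(path), RUN_HEADER)
    return [
        RunResult(
            activity=str(r.activity), window_size=int(r.window_size),
            fold=int(r.fold), iteration=int(r.iteration),
            auc=float(r.auc), accuracy=float(r.accuracy),
            n_test_windows=int(r.n_test_windows),
            n_test_positives=int(r.n_test_positives),
        )
        for r in df.itertuples(index=False)
    ]


def write_activity_table(results: Sequence[ActivityResult], path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([r.__dict__ for r in results], columns=list(ACTIVITY_HEADER))
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def write_fits(fits: Sequence[WindowSizeFit], path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in fits:
        b0, b1, b2 = f.coefficients
        rows.append(
            (f.activity, b0, b1, b2, f.r2, f.adjusted_r2,
             f.effect_size, f.local_max_window, f.relevant)
        )
    pd.DataFrame(rows, columns=list(FIT_HEADER)).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path
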