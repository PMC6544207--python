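"""Reading and writing gaze sample streams, session metadata and feature tables.

File formats (all delimiter-separated text with a header):

* gaze sample file — columns ``time_s, gaze_x_cm, gaze_y_cm, pupil_mm``;
  gaze coordinates are in cm relative to the screen center (right/up
  positive), pupil diameter in mm with 0 meaning closed eye / missing
  pupil image;
* annotation sidecar — columns ``label, start_s, end_s`` with half-open
  intervals ``[start, end)`` and labels ``cycle:<k>``, ``kss_pause`` or
  ``micro_break``;
* feature table — one row per segment, the 32 oculometric columns in
  :data:`oculofatigue.oculometrics.FEATURE_COLUMNS` order plus
  ``age, sex, kss, label`` and the ``participant_id, segment_index`` keys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from oculofatigue.errors import FormatError, IntegrityError, ValidationError

GAZE_COLUMNS = ["time_s", "gaze_x_cm", "gaze_y_cm", "pupil_mm"]
ANNOTATION_COLUMNS = ["label", "start_s", "end_s"]

#: Labels fatigued/alert derive from KSS at this threshold by default.
DEFAULT_KSS_THRESHOLD = 5

LABEL_FATIGUED = "fatigued"
LABEL_ALERT = "alert"


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical viewing geometry used to convert cm to visual angle."""

    viewing_distance_cm: float
    screen_width_cm: float = 37.6
    screen_height_cm: float = 30.1

    def __post_init__(self) -> None:
        if self.viewing_distance_cm <= 0:
            raise ValidationError(
                f"viewing distance must be positive, got {self.viewing_distance_cm}"
            )


@dataclass(frozen=True)
class Interval:
    """Half-open labeled time interval [start_s, end_s)."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"interval {self.label!r}: end {self.end_s} must exceed start {self.start_s}"
            )

    def contains(self, t: np.ndarray) -> np.ndarray:
        return (t >= self.start_s) & (t < self.end_s)


@dataclass
class GazeRecording:
    """A time-stamped gaze/pupil sample stream with session annotations."""

    timestamps: np.ndarray
    gaze_xy: np.ndarray
    pupil_mm: np.ndarray
    geometry: ScreenGeometry
    annotations: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.gaze_xy = np.asarray(self.gaze_xy, dtype=float)
        self.pupil_mm = np.asarray(self.pupil_mm, dtype=float)
        n = self.timestamps.size
        if self.gaze_xy.shape != (n, 2):
            raise ValidationError(
                f"gaze_xy must have shape ({n}, 2), got {self.gaze_xy.shape}"
            )
        if self.pupil_mm.shape != (n,):
            raise ValidationError("pupil_mm length must match timestamps")
        dt = np.diff(self.timestamps)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise IntegrityError(
                f"timestamps not strictly increasing at row {int(bad[0]) + 2}"
            )
        if np.any(self.pupil_mm < 0):
            i = int(np.nonzero(self.pupil_mm < 0)[0][0])
            raise ValidationError(f"negative pupil diameter at sample {i}")
        _check_annotation_overlap(self.annotations)

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def sampling_rate_hz(self) -> float:
        """Median sampling rate of the stream."""
        if len(self) < 2:
            raise ValidationError("need >= 2 samples to estimate sampling rate")
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    def intervals(self, label_prefix: str) -> list[Interval]:
        return [a for a in self.annotations if a.label.startswith(label_prefix)]

    def cycle_intervals(self, segment_index: int, cycles_per_segment: int = 20) -> list[Interval]:
        """Cycle intervals belonging to 1-based segment ``segment_index``."""
        lo = (segment_index - 1) * cycles_per_segment + 1
        hi = segment_index * cycles_per_segment
        out = []
        for a in self.annotations:
            if a.label.startswith("cycle:"):
                k = int(a.label.split(":", 1)[1])
                if lo <= k <= hi:
                    out.append(a)
        return sorted(out, key=lambda a: a.start_s)


def _check_annotation_overlap(annotations: Sequence[Interval]) -> None:
    by_class: dict[str, list[Interval]] = {}
    for a in annotations:
        cls = "cycle" if a.label.startswith("cycle:") else a.label
        by_class.setdefault(cls, []).append(a)
    for cls, ivs in by_class.items():
        ivs = sorted(ivs, key=lambda a: a.start_s)
        for prev, nxt in zip(ivs, ivs[1:]):
            if nxt.start_s < prev.end_s:
                raise IntegrityError(
                    f"annotations overlap within class {cls!r}: "
                    f"[{prev.start_s}, {prev.end_s}) and [{nxt.start_s}, {nxt.end_s})"
                )


@dataclass
class SessionMeta:
    """Per-session metadata: who, which mode, and the KSS trace."""

    participant_id: str
    age: float
    sex: str
    mode: str = "automatic"
    kss_by_segment: list[int] = field(default_factory=list)
    cycle_count: int = 180
    cycles_per_segment: int = 20

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.mode not in ("manual", "automatic"):
            raise ValidationError(f"mode must be 'manual' or 'automatic', got {self.mode!r}")
        for k in self.kss_by_segment:
            if not 1 <= k <= 10:
                raise ValidationError(f"KSS rating {k} outside [1, 10]")
        if self.cycle_count % self.cycles_per_segment != 0:
            raise ValidationError(
                f"cycle_count {self.cycle_count} not divisible by "
                f"cycles_per_segment {self.cycles_per_segment}"
            )

    @property
    def n_segments(self) -> int:
        return self.cycle_count // self.cycles_per_segment


class LabeledDataset:
    """Participants x segments feature matrix with KSS scores and labels.

    Thin wrapper over a :class:`pandas.DataFrame` whose columns are
    ``participant_id, segment_index, <32 features>, age, sex, kss, label``.
    The label column is always derived from ``kss`` at ``kss_threshold``.
    """

    def __init__(self, frame: pd.DataFrame, kss_threshold: int = DEFAULT_KSS_THRESHOLD):
        from oculofatigue.oculometrics import FEATURE_COLUMNS

        frame = frame.copy()
        required = ["participant_id", "segment_index", "kss"]
        for col in required:
            if col not in frame.columns:
                raise FormatError(f"feature table missing required column {col!r}")
        if len(frame):
            kss = frame["kss"].to_numpy()
            bad = (kss < 1) | (kss > 10) | ~np.isfinite(kss.astype(float))
            if np.any(bad):
                raise ValidationError(
                    f"KSS value {kss[np.nonzero(bad)[0][0]]!r} outside [1, 10]"
                )
        known = set(FEATURE_COLUMNS) | {"participant_id", "segment_index",
                                        "age", "sex", "kss", "label"}
        unknown = [c for c in frame.columns if c not in known]
        if unknown:
            warnings.warn(f"ignoring unknown feature columns: {unknown}", stacklevel=2)
            frame = frame.drop(columns=unknown)
        for col in FEATURE_COLUMNS + ["age"]:
            if col not in frame.columns:
                frame[col] = np.nan
        if "sex" not in frame.columns:
            frame["sex"] = "F"
        # labels are never trusted from file: recomputed from kss
        frame["label"] = np.where(
            frame["kss"].astype(float) >= kss_threshold, LABEL_FATIGUED, LABEL_ALERT
        )
        order = (["participant_id", "segment_index"] + FEATURE_COLUMNS
                 + ["age", "sex", "kss", "label"])
        self.frame = frame[order].reset_index(drop=True)
        self.kss_threshold = int(kss_threshold)
        dup = self.frame.duplicated(subset=["participant_id", "segment_index"])
        if dup.any():
            raise IntegrityError("duplicate (participant, segment) rows in dataset")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def participants(self) -> list[str]:
        return list(pd.unique(self.frame["participant_id"]))

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def feature_matrix(self, features: Sequence[str] | None = None) -> pd.DataFrame:
        """Numeric model inputs (sex encoded F=0, M=1)."""
        from oculofatigue.oculometrics import FEATURE_COLUMNS

        if features is None:
            features = FEATURE_COLUMNS + ["age", "sex"]
        X = self.frame[list(features)].copy()
        if "sex" in X.columns:
            X["sex"] = X["sex"].map({"F": 0.0, "M": 1.0})
        return X.astype(float)


def read_gaze_recording(
    path: str | Path,
    geometry: ScreenGeometry,
    annotations_path: str | Path | None = None,
) -> GazeRecording:
    """Read a gaze sample file (and its annotation sidecar, if present).

    The sidecar defaults to ``<stem>.annotations.csv`` next to the sample
    file and is optional.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in GAZE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"gaze file {path.name} missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise IntegrityError(
            f"{path.name}: time not strictly increasing at row {int(bad[0]) + 2}"
        )
    if np.any(df["pupil_mm"].to_numpy() < 0):
        raise ValidationError(f"{path.name}: pupil_mm contains negative values")

    if annotations_path is None:
        candidate = path.parent / (path.stem + ".annotations.csv")
        annotations_path = candidate if candidate.exists() else None
    annotations: list[Interval] = []
    if annotations_path is not None:
        adf = pd.read_csv(annotations_path, comment="#")
        for col in ANNOTATION_COLUMNS:
            if col not in adf.columns:
                raise FormatError(
                    f"annotation file missing column {col!r}"
                )
        annotations = [
            Interval(str(r.label), float(r.start_s), float(r.end_s))
            for r in adf.itertuples()
        ]
    return GazeRecording(
        timestamps=t,
        gaze_xy=df[["gaze_x_cm", "gaze_y_cm"]].to_numpy(dtype=float),
        pupil_mm=df["pupil_mm"].to_numpy(dtype=float),
        geometry=geometry,
        annotations=annotations,
    )


def write_gaze_recording(
    recording: GazeRecording,
    path: str | Path,
    annotations_path: str | Path | None = None,
    header_lines: Sequence[str] = (),
) -> Path:
    """Write a recording (and its annotations, if any) as CSV; returns path."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": recording.timestamps,
        "gaze_x_cm": recording.gaze_xy[:, 0],
        "gaze_y_cm": recording.gaze_xy[:, 1],
        "pupil_mm": recording.pupil_mm,
    })
    _write_csv_with_header(df, path, header_lines)
    if recording.annotations:
        if annotations_path is None:
            annotations_path = path.parent / (path.stem + ".annotations.csv")
        adf = pd.DataFrame(
            [(a.label, a.start_s, a.end_s) for a in recording.annotations],
            columns=ANNOTATION_COLUMNS,
        )
        _write_csv_with_header(adf, Path(annotations_path), header_lines)
    return path


def load_dataset(path: str | Path, kss_threshold: int = DEFAULT_KSS_THRESHOLD) -> LabeledDataset:
    """Load a feature table; labels are recomputed from kss at ``kss_threshold``."""
    df = pd.read_csv(path, comment="#")
    if len(df) == 0 and "participant_id" not in df.columns:
        raise FormatError(f"{path}: empty file without header")
    return LabeledDataset(df, kss_threshold=kss_threshold)


def write_features_table(
    dataset: LabeledDataset,
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> Path:
    """Write a dataset as CSV in the documented column order (lossless round-trip)."""
    path = Path(path)
    _write_csv_with_header(dataset.frame, path, header_lines)
    return path


def _write_csv_with_header(df: pd.DataFrame, path: Path, header_lines: Sequence[str]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
    tmp.replace(path)
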