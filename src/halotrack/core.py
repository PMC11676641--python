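"""Core data containers shared across the pipeline: tracks and image stacks.

Conventions used throughout the package:

* coordinates are metric (micrometres), x to the right, y downward, with the
  origin at the centre of the top-left pixel of the recording;
* frame indices are 0-based and times are ``t = frame_index / frame_rate``
  seconds from the first frame;
* a track is the atomic unit of motility analysis: the time-ordered 2-D
  positions of one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "Track",
    "ImageStack",
    "tracks_to_frame",
    "tracks_to_csv",
    "tracks_from_csv",
]

#: Columns of the tracks CSV interchange format.
TRACK_CSV_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


class SchemaError(ValueError):
    """A tabular input does not match the expected schema."""


@dataclass
class Track:
    """Time-ordered 2-D positions of a single cell, in micrometres."""

    track_id: str
    frames: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    recording_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frames)
        if not (len(self.t) == len(self.x) == len(self.y) == n):
            raise ValueError("frames, t, x and y must have equal length")
        if n == 0:
            raise ValueError("empty track")
        if n > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError(
                f"track {self.track_id!r}: frame indices must be strictly increasing"
            )
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError(
                f"track {self.track_id!r}: timestamps must be strictly increasing"
            )

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of [x, y] positions in micrometres."""
        return np.column_stack([self.x, self.y])

    @property
    def duration(self) -> float:
        """Elapsed time between first and last point, seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def qualified_id(self) -> str:
        """Track id namespaced by its recording, unique across a campaign."""
        return f"{self.recording_id}/{self.track_id}" if self.recording_id else self.track_id


@dataclass
class ImageStack:
    """A time-lapse recording: frames plus the metadata the analysis needs.

    ``frames`` is a (T, H, W) float32 array of intensities.  ``frame_rate``
    is the exact rate of this recording in Hz (the analysis never assumes a
    nominal rate) and ``pixel_size`` converts pixels to micrometres.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.shape[0] < 2:
            raise ValueError("an image stack needs at least 2 frames")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])

    @property
    def duration(self) -> float:
        """Recording duration in seconds (first to last frame)."""
        return (self.n_frames - 1) / self.frame_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks into a tidy table (one row per track point)."""
    rows = []
    for tr in tracks:
        flag = tr.meta.get("motile")
        for i in range(tr.n_points):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "recording_id": tr.recording_id,
                    "frame": int(tr.frames[i]),
                    "t_s": tr.t[i],
                    "x_um": tr.x[i],
                    "y_um": tr.y[i],
                    "motile_flag": flag,
                }
            )
    columns = ["track_id", "recording_id", "frame", "t_s", "x_um", "y_um", "motile_flag"]
    return pd.DataFrame(rows, columns=columns)


def tracks_to_csv(tracks: list[Track], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def tracks_from_csv(path: str | Path) -> list[Track]:
    """Read tracks from CSV, validating the schema.

    Raises :class:`SchemaError` naming the offending column or row when the
    file is malformed (missing columns, non-numeric values, out-of-order
    frames within a track).
    """
    # round_trip parsing: exported coordinates must reload bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"tracks CSV {path}: missing column(s) {missing}")
    for col in ["frame", "t_s", "x_um", "y_um"]:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"tracks CSV {path}: non-numeric value in column {col!r} at row {row}")
        if values.isna().any():
            row = int(values.isna().idxmax())
            raise SchemaError(f"tracks CSV {path}: missing value in column {col!r} at row {row}")
        df[col] = values
    has_rec = "recording_id" in df.columns
    has_flag = "motile_flag" in df.columns
    tracks: list[Track] = []
    group_cols = ["recording_id", "track_id"] if has_rec else ["track_id"]
    if has_rec:
        df["recording_id"] = df["recording_id"].fillna("")
    for key, g in df.groupby(group_cols, sort=False):
        frames = g["frame"].to_numpy()
        if len(frames) > 1 and not np.all(np.diff(frames) > 0):
            raise SchemaError(
                f"tracks CSV {path}: track {key!r} has out-of-order or duplicate frames"
            )
        meta = {}
        if has_flag and g["motile_flag"].notna().any():
            meta["motile"] = bool(g["motile_flag"].iloc[0])
        rec = str(key[0]) if has_rec else ""
        tid = str(key[-1]) if isinstance(key, tuple) else str(key)
        tracks.append(
            Track(
                track_id=tid,
                frames=frames,
                t=g["t_s"].to_numpy(),
                x=g["x_um"].to_numpy(),
                y=g["y_um"].to_numpy(),
                recording_id=rec,
                meta=meta,
            )
        )
    return tracks
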