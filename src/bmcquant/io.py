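"""Image-series and table I/O.

TIFF stacks are read page-per-frame with axis order (time, row, col);
calibration (pixel size, frame interval) always comes from config or flags,
never from embedded metadata — proprietary microscope formats are out of
scope.  Tables are plain CSV written through pandas with >= 6 significant
digits so round trips preserve every reported quantity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InputError


@dataclass
class ImageSeries:
    """A time-ordered stack of single-channel intensity frames.

    Parameters
    ----------
    frames
        Array of shape (time, rows, cols), non-negative intensities
        (integer pixel data is converted to float without rescaling).
    channel_label
        Free-text channel name, e.g. ``"shell"`` or ``"cargo"``.
    pixel_size
        μm per pixel (> 0).
    frame_interval
        s per frame (> 0).
    timestamps
        Optional per-frame acquisition times in s; defaults to
        ``arange(T) * frame_interval``.  Must be strictly increasing.
    """

    frames: np.ndarray
    channel_label: str = ""
    pixel_size: float = 1.0
    frame_interval: float = 1.0
    timestamps: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise InputError(
                f"frames must be (time, rows, cols), got shape {self.frames.shape}"
            )
        if np.any(self.frames < 0):
            raise InputError("intensities must be non-negative")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise InputError("pixel_size and frame_interval must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(self.n_frames) * float(self.frame_interval)
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.n_frames,):
                raise InputError(
                    f"timestamps length {self.timestamps.size} != frame count "
                    f"{self.n_frames}"
                )
            if np.any(np.diff(self.timestamps) <= 0):
                raise InputError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


def read_image_series(
    path: str | Path,
    pixel_size: float,
    frame_interval: float,
    channel_axis: int | None = None,
    channel_labels: tuple[str, ...] | None = None,
) -> ImageSeries | list[ImageSeries]:
    """Read a TIFF stack into one :class:`ImageSeries` per channel.

    A plain multi-page TIFF is interpreted as (time, row, col).  For a
    two-channel file the channel axis must be declared explicitly via
    ``channel_axis`` (mixed dialects are rejected rather than guessed); one
    series per channel is returned, in axis order.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except FileNotFoundError as e:
        raise IOError(f"cannot read image file: {path}") from e
    except Exception as e:  # truncated / malformed TIFF
        raise IOError(f"unreadable TIFF file {path}: {e}") from e
    data = np.asarray(data)
    if data.size == 0:
        raise IOError(f"unreadable TIFF file {path}: no image data (truncated?)")
    if channel_axis is None:
        if data.ndim not in (2, 3):
            raise FormatError(
                f"{path}: expected (time, row, col) pages, got shape {data.shape}; "
                "declare channel_axis for multichannel files"
            )
        return ImageSeries(data.astype(float), path.stem, pixel_size, frame_interval)
    if data.ndim != 4:
        raise FormatError(
            f"{path}: channel_axis declared but data is {data.ndim}D "
            f"(shape {data.shape}); expected 4D"
        )
    data = np.moveaxis(data, channel_axis, 0)
    labels = channel_labels or tuple(f"{path.stem}_ch{i}" for i in range(data.shape[0]))
    if len(labels) != data.shape[0]:
        raise FormatError(
            f"{path}: {len(labels)} channel labels for {data.shape[0]} channels"
        )
    return [
        ImageSeries(data[i].astype(float), labels[i], pixel_size, frame_interval)
        for i in range(data.shape[0])
    ]


def write_image_series(series: ImageSeries, path: str | Path) -> None:
    """Write a series as an uncompressed 16-bit multi-page TIFF.

    Intensities are rounded and clipped to the uint16 range; generators keep
    their dynamic range well inside it.
    """
    data = np.clip(np.round(series.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def write_results_table(records: list[dict], path: str | Path) -> None:
    """Write result mappings as CSV, one row per record, input order.

    All records must share a key set; floats keep >= 6 significant digits.
    """
    path = Path(path)
    if records:
        keys = list(records[0].keys())
        for r in records[1:]:
            if list(r.keys()) != keys:
                raise InputError("records do not share a key set")
        df = pd.DataFrame(records, columns=keys)
    else:
        df = pd.DataFrame()
    try:
        df.to_csv(path, index=False, float_format="%.8g")
    except OSError as e:
        raise IOError(f"cannot write results table to {path}: {e}") from e


def read_results_table(path: str | Path) -> list[dict]:
    """Inverse of :func:`write_results_table`."""
    try:
        df = pd.read_csv(Path(path))
    except pd.errors.EmptyDataError:
        return []
    return df.to_dict(orient="records")


def write_ground_truth(params: dict, path: str | Path) -> None:
    """Serialize generator ground truth as a two-column parameter,value CSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["parameter", "value"])
        for k, v in params.items():
            w.writerow([k, repr(v) if isinstance(v, str) else f"{v:.10g}"])


def write_profile_csv(
    positions: np.ndarray, profiles: np.ndarray, path: str | Path
) -> None:
    """Write per-frame axial profiles: columns position_um, frame_0, frame_1, ..."""
    cols = {"position_um": np.asarray(positions, dtype=float)}
    for i, prof in enumerate(np.asarray(profiles, dtype=float)):
        cols[f"frame_{i}"] = prof
    pd.DataFrame(cols).to_csv(Path(path), index=False, float_format="%.8g")


def read_profile_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an axial-profile CSV; returns (positions_um, profiles[T, X])."""
    df = pd.read_csv(Path(path))
    if "position_um" not in df.columns:
        raise FormatError(f"{path}: missing position_um column")
    frame_cols = [c for c in df.columns if c.startswith("frame_")]
    frame_cols.sort(key=lambda c: int(c.split("_")[1]))
    if not frame_cols:
        raise FormatError(f"{path}: no frame_<i> columns")
    positions = df["position_um"].to_numpy(dtype=float)
    profiles = np.stack([df[c].to_numpy(dtype=float) for c in frame_cols])
    return positions, profiles
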