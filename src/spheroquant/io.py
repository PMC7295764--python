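"""Calibrated image and trajectory I/O.

All downstream analysis works in physical units (µm, minutes); pixel and
frame-index conversions happen only at this boundary.  Coordinate
convention: pixel (0, 0) is top-left, pixel centers, x runs along columns
and y along rows, so x = col * pixel_size and y = row * pixel_size.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageSeries",
    "TrajectorySet",
    "read_image_series",
    "write_image_series",
    "read_trajectories",
    "write_trajectories",
    "load_config",
]


@dataclasses.dataclass
class ImageSeries:
    """A calibrated multi-frame (optionally multi-channel) image stack.

    Parameters
    ----------
    pixels
        Array of shape (frames, rows, cols) or (frames, rows, cols,
        channels), non-negative intensities.
    pixel_size
        Physical size of one pixel, µm.
    frame_interval
        Time between consecutive frames, minutes.
    channel_names
        Labels for the channel axis; required when pixels has 4 dims.
    """

    pixels: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (3, 4):
            raise ValueError("pixels must be (T, R, C) or (T, R, C, K)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (µm/pixel)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (minutes)")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixels.ndim == 4:
            if len(self.channel_names) != self.pixels.shape[-1]:
                raise ValueError("channel_names must match channel axis")
        self.channel_names = tuple(self.channel_names)

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    @property
    def duration(self) -> float:
        """Total acquisition span in minutes ((n_frames - 1) * interval)."""
        return (self.n_frames - 1) * self.frame_interval

    def channel(self, name: str | None = None) -> np.ndarray:
        """Return the (T, R, C) array for one channel (or the only one)."""
        if self.pixels.ndim == 3:
            if name is not None and self.channel_names and name not in self.channel_names:
                raise KeyError(f"unknown channel {name!r}")
            return self.pixels
        if name is None:
            if self.pixels.shape[-1] == 1:
                return self.pixels[..., 0]
            raise ValueError("multi-channel series: channel name required")
        try:
            k = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None
        return self.pixels[..., k]


@dataclasses.dataclass
class TrajectorySet:
    """Per-cell tracks as a tidy table of (cell_id, frame, x, y) in µm."""

    data: pd.DataFrame
    frame_interval: float
    condition: str = ""

    REQUIRED = ("cell_id", "frame", "x", "y")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (minutes)")
        df = df.sort_values(["cell_id", "frame"], kind="stable").reset_index(drop=True)
        if df.duplicated(["cell_id", "frame"]).any():
            raise ValueError("duplicate (cell_id, frame) records")
        self.data = df

    @property
    def n_cells(self) -> int:
        return self.data["cell_id"].nunique()

    def cells_with_gaps(self) -> list:
        """cell_ids whose frame sequence skips at least one frame."""
        out = []
        for cid, grp in self.data.groupby("cell_id", sort=False):
            if np.any(np.diff(grp["frame"].to_numpy()) > 1):
                out.append(cid)
        return out

    def __len__(self) -> int:
        return len(self.data)


def write_image_series(series: ImageSeries, path: str | Path) -> list[Path]:
    """Write one multi-page TIFF per channel, frame-major.

    ``path`` is a stem; single-channel series go to ``<stem>.tif``,
    multi-channel to ``<stem>_<channel>.tif``.  Calibration metadata is
    stored in the TIFF description.  Returns the written paths.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "pixel_size_um": float(series.pixel_size),
        "frame_interval_min": float(series.frame_interval),
    }
    written = []
    if series.pixels.ndim == 3:
        p = path.with_suffix(".tif")
        tifffile.imwrite(p, np.asarray(series.pixels, dtype=np.float32),
                         photometric="minisblack",
                         description=yaml.safe_dump(meta))
        written.append(p)
    else:
        for k, name in enumerate(series.channel_names):
            p = path.parent / f"{path.stem}_{name}.tif"
            tifffile.imwrite(p, np.asarray(series.pixels[..., k], dtype=np.float32),
                             photometric="minisblack",
                             description=yaml.safe_dump({**meta, "channel": name}))
            written.append(p)
    return written


def read_image_series(
    paths: str | Path | Sequence[str | Path],
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageSeries:
    """Read one or several single-channel multi-page TIFFs as an ImageSeries.

    Calibration (pixel size and frame interval) must be supplied or be
    present in the TIFF description written by :func:`write_image_series`;
    guessing physical units is a hard error.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    stacks, names = [], []
    for p in paths:
        p = Path(p)
        with tifffile.TiffFile(p) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description or ""
        meta = {}
        if desc:
            try:
                meta = yaml.safe_load(desc) or {}
            except yaml.YAMLError:
                meta = {}
        if not isinstance(meta, dict):
            meta = {}
        if pixel_size is None:
            pixel_size = meta.get("pixel_size_um")
        if frame_interval is None:
            frame_interval = meta.get("frame_interval_min")
        if arr.ndim == 2:
            arr = arr[None]
        stacks.append(np.asarray(arr, dtype=float))
        names.append(meta.get("channel", p.stem))
    if pixel_size is None or frame_interval is None:
        raise ValueError(
            "calibration (pixel_size, frame_interval) neither supplied nor "
            "embedded; refusing to guess physical units"
        )
    shape0 = stacks[0].shape
    for s in stacks[1:]:
        if s.shape != shape0:
            raise ValueError("channel stacks have mismatched shapes")
    for s in stacks:
        if any(f.shape != s.shape[1:] for f in s):
            raise ValueError("frames within a stack have mismatched shapes")
    if len(stacks) == 1:
        return ImageSeries(stacks[0], float(pixel_size), float(frame_interval))
    pixels = np.stack(stacks, axis=-1)
    if channel_names is None:
        channel_names = names
    return ImageSeries(pixels, float(pixel_size), float(frame_interval),
                       tuple(channel_names))


def write_trajectories(ts: TrajectorySet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ts.data[list(TrajectorySet.REQUIRED)].to_csv(path, index=False)
    return path


def read_trajectories(
    path: str | Path, frame_interval: float, condition: str = ""
) -> TrajectorySet:
    """Read a delimited trajectory table (header: cell_id, frame, x, y)."""
    df = pd.read_csv(path)
    return TrajectorySet(df, frame_interval=frame_interval, condition=condition)


def load_config(path: str | Path) -> dict:
    """Load a structured-text (YAML) run configuration as a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg
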