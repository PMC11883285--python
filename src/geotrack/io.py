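"""Video frames and coordinate-matrix I/O.

Videos come in either as standard containers (MP4/AVI, decoded through
imageio if a suitable backend is available) or as a directory of
lexicographically ordered PNG/TIFF frames.  All frames are converted to
grayscale floats in [0, 1] on read, whatever the source bit depth.

Tracked coordinates are exchanged as plain CSV (RFC 4180, header row
mandatory) with one row per (frame, fly): ``frame_index, fly_id, x_px,
y_px, observed``.  Coordinates are stored to 2 decimal pixels; the
``observed`` flag distinguishes real detections from coasted/backfilled
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import ROI

_FRAME_SUFFIXES = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")


@dataclass
class FrameStack:
    """An ordered stack of grayscale frames, values normalized to [0, 1]."""

    frames: np.ndarray  # (n_frames, height, width) float64 in [0, 1]
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (n, h, w), got shape {self.frames.shape}")
        if self.frames.size and (self.frames.min() < 0 or self.frames.max() > 1):
            raise ValueError("frame values must lie in [0, 1]")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each frame."""
        return self.frames.shape[1], self.frames.shape[2]


def _to_gray_unit(img: np.ndarray) -> np.ndarray:
    """Grayscale (channel mean) + normalize by the dtype's full scale."""
    arr = np.asarray(img)
    if arr.ndim == 3:  # color -> channel mean
        arr = arr.mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        return arr.astype(float) / scale
    arr = arr.astype(float)
    if arr.size and arr.max() > 1.0:  # float frames already on an 8-bit scale
        return np.clip(arr / 255.0, 0.0, 1.0)
    return np.clip(arr, 0.0, 1.0)


def read_video(path: str | Path, frame_rate_hz: float = 30.0) -> FrameStack:
    """Read an MP4/AVI file or a directory of image frames into a FrameStack.

    Directory frames are taken in lexicographic filename order.  Raises if
    the source yields fewer than two frames or cannot be decoded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video path not found: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise ValueError(f"no image frames found in directory {path}")
        frames = [_to_gray_unit(iio.imread(f)) for f in files]
    else:
        try:
            frames = [_to_gray_unit(f) for f in iio.imiter(path)]
        except Exception as exc:  # no backend / broken container
            raise ValueError(f"could not decode video file {path}: {exc}") from exc
    if len(frames) < 2:
        raise ValueError(f"video {path} has {len(frames)} frame(s); need at least 2")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames have inconsistent dimensions: {sorted(shapes)}")
    return FrameStack(np.stack(frames), frame_rate_hz=frame_rate_hz)


def write_frames(stack: FrameStack, directory: str | Path, prefix: str = "frame") -> list[Path]:
    """Write a stack as zero-padded 8-bit PNG frames (debug/export helper)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(stack) - 1)))
    paths = []
    for i, frame in enumerate(stack.frames):
        p = directory / f"{prefix}_{i:0{width}d}.png"
        iio.imwrite(p, (np.clip(frame, 0, 1) * 255).round().astype(np.uint8))
        paths.append(p)
    return paths


def crop_roi(stack: FrameStack, roi: ROI) -> FrameStack:
    """Crop every frame to the ROI rectangle (half-open, image convention)."""
    h, w = stack.shape
    if roi.x0 + roi.width > w or roi.y0 + roi.height > h:
        raise ValueError(
            f"ROI {roi} exceeds frame bounds {h}x{w} (rows x cols)"
        )
    cropped = stack.frames[:, roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    return FrameStack(cropped.copy(), frame_rate_hz=stack.frame_rate_hz)


@dataclass
class CoordinateMatrix:
    """Finalized per-fly positions: one (x_px, y_px) per fly per frame.

    ``positions`` has shape (n_flies, n_frames, 2) in image-convention
    pixels.  ``observed`` marks which entries came from an assigned
    detection (False = coasted on last known coordinates, backfilled before
    track birth, or bottom-seeded for a never-detected fly).
    """

    positions: np.ndarray
    vial_id: int = 0
    observed: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError(
                f"positions must be (n_flies, n_frames, 2), got {self.positions.shape}"
            )
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values")
        if self.observed is None:
            self.observed = np.ones(self.positions.shape[:2], dtype=bool)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != self.positions.shape[:2]:
                raise ValueError("observed mask shape must match (n_flies, n_frames)")

    @property
    def n_flies(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]


def write_coordinates(matrix: CoordinateMatrix, path: str | Path) -> None:
    """Write a coordinate matrix as tidy CSV (2-decimal pixel precision)."""
    n_flies, n_frames = matrix.n_flies, matrix.n_frames
    frames = np.repeat(np.arange(n_frames), n_flies)
    flies = np.tile(np.arange(n_flies), n_frames)
    df = pd.DataFrame(
        {
            "frame_index": frames,
            "fly_id": flies,
            "x_px": matrix.positions[flies, frames, 0].round(2),
            "y_px": matrix.positions[flies, frames, 1].round(2),
            "observed": matrix.observed[flies, frames].astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_coordinates(path: str | Path) -> CoordinateMatrix:
    """Read a coordinate CSV back; validates completeness per frame."""
    df = pd.read_csv(path)
    required = {"frame_index", "fly_id", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coordinate CSV {path} missing column(s): {sorted(missing)}")
    if df.empty:
        raise ValueError(f"coordinate CSV {path} has no data rows")
    fly_ids = np.sort(df["fly_id"].unique())
    n_flies = len(fly_ids)
    if not np.array_equal(fly_ids, np.arange(n_flies)):
        raise ValueError(f"fly_id values must be dense 0..{n_flies - 1}, got {fly_ids}")
    frames = np.sort(df["frame_index"].unique())
    n_frames = len(frames)
    if not np.array_equal(frames, np.arange(n_frames)):
        raise ValueError("frame_index values must be dense 0..n_frames-1")
    counts = df.groupby("frame_index")["fly_id"].nunique()
    bad = counts[counts != n_flies]
    if not bad.empty:
        raise ValueError(
            f"frame {bad.index[0]} has {bad.iloc[0]} flies, expected {n_flies}"
        )
    positions = np.full((n_flies, n_frames, 2), np.nan)
    observed = np.ones((n_flies, n_frames), dtype=bool)
    positions[df["fly_id"], df["frame_index"], 0] = df["x_px"]
    positions[df["fly_id"], df["frame_index"], 1] = df["y_px"]
    if "observed" in df.columns:
        observed[df["fly_id"], df["frame_index"]] = df["observed"].astype(bool)
    return CoordinateMatrix(positions=positions, observed=observed)
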