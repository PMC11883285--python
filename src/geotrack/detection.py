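"""Per-frame fly detection by median-background subtraction.

The flies appear as dark elliptical blobs on a bright backlit field, so a
static background is estimated as the per-pixel median over all frames of
a vial video; each frame is then subtracted from the background and
differences above a fixed threshold (default 0.06 in normalized units)
mark moving dark objects.  Connected components of the binary mask are
measured (centroid, area, ellipse-equivalent axis lengths) and classified
against the calibration thresholds.  A blob in the multi-fly size range
contributes k = ceil(area / max-single-area) individual detections, all
carrying the blob centroid, so that downstream tracking always deals in
individual flies.

Frames are processed independently; there is no temporal smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .calibration import DetectionThresholds, classify_object
from .io import FrameStack

# tolerance when the multi-blob area is an exact multiple of the single-fly
# maximum: ceil must not invent a phantom extra fly from float round-off
_CEIL_EPS = 1e-9


@dataclass(frozen=True)
class ObjectProps:
    """One connected component of a segmented frame."""

    centroid: tuple[float, float]  # (x_px, y_px)
    area_px: int
    major_axis_px: float
    minor_axis_px: float


@dataclass(frozen=True)
class Detection:
    """One candidate fly; multiplicity > 1 means a split multi-fly blob."""

    centroid: tuple[float, float]
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity}")


def compute_background(stack: FrameStack) -> np.ndarray:
    """Per-pixel median over all frames (even counts -> midpoint mean)."""
    if len(stack) < 3:
        raise ValueError(f"need >= 3 frames for a background, got {len(stack)}")
    return np.median(stack.frames, axis=0)


def segment_frame(
    frame: np.ndarray, background: np.ndarray, diff_threshold: float = 0.06
) -> np.ndarray:
    """Binary mask of pixels darker than background by more than the threshold.

    The subtraction direction is background − frame: flies are dark on a
    bright field.  Differences ≤ diff_threshold are background (the
    threshold itself is inclusive on the background side).
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs background {background.shape}")
    # small slack keeps a difference of exactly diff_threshold on the
    # background side despite float round-off
    return (background - frame) > diff_threshold + 1e-9


def extract_objects(mask: np.ndarray, connectivity: int = 2) -> list[ObjectProps]:
    """Measure connected components of a binary mask.

    Centroid is the mean of member pixel coordinates; axis lengths are
    those of the ellipse with the same second central moments as the
    component (8-connected by default).
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=connectivity)
    props = measure.regionprops(labels)
    out = []
    for p in props:
        row, col = p.centroid
        out.append(
            ObjectProps(
                centroid=(float(col), float(row)),
                area_px=int(p.area),
                major_axis_px=float(p.axis_major_length),
                minor_axis_px=float(p.axis_minor_length),
            )
        )
    return out


def detect_flies(
    objects: list[ObjectProps], thresholds: DetectionThresholds
) -> list[Detection]:
    """Turn measured objects into individual-fly detections.

    Noise objects are dropped; single-fly objects yield one detection;
    multi-fly objects yield k = ceil(area / area_single_max_px) detections
    sharing the blob centroid (exact integer quotients stay at that
    integer).
    """
    detections = []
    for obj in objects:
        cls = classify_object(
            obj.area_px, obj.minor_axis_px, obj.major_axis_px, thresholds
        )
        if cls == "noise":
            continue
        if cls == "single":
            detections.append(Detection(centroid=obj.centroid, multiplicity=1))
        else:
            k = int(np.ceil(obj.area_px / thresholds.area_single_max_px - _CEIL_EPS))
            detections.append(Detection(centroid=obj.centroid, multiplicity=max(k, 2)))
    return detections


def detect_frame(
    frame: np.ndarray,
    background: np.ndarray,
    thresholds: DetectionThresholds,
    diff_threshold: float = 0.06,
    connectivity: int = 2,
) -> list[Detection]:
    """Full single-frame pipeline: segment → measure → classify/split."""
    mask = segment_frame(frame, background, diff_threshold)
    return detect_flies(extract_objects(mask, connectivity), thresholds)


def expand_detections(detections: list[Detection]) -> np.ndarray:
    """Flatten detections into an (n, 2) array of individual-fly points.

    A multiplicity-k detection contributes k identical rows (a merged blob
    gives every occupant the common centroid).
    """
    points = [d.centroid for d in detections for _ in range(d.multiplicity)]
    return np.array(points, dtype=float).reshape(-1, 2)
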