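"""Size/shape calibration for fly detection.

Before tracking a new strain or camera setup, a sample of segmented
objects is labeled as a single fly, multiple touching flies, or noise.
From those labels two families of thresholds are derived:

* area cut-offs — objects smaller than the lowest 16% of single-fly areas
  or larger than the largest multi-fly area are noise; the largest
  single-fly area is the boundary between the single and multi classes;
* axis-ratio intervals — the observed [min, max] range of
  minor/major-axis ratios per class; an object whose ratio falls outside
  its area-candidate class's interval is demoted to noise.

Labels are supplied as a CSV (``area_px, major_axis_px, minor_axis_px,
label``), replacing any interactive labeling step; thresholds serialize to
JSON so one calibration can drive many runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

LABELS = ("single", "multi", "noise")


class CalibrationError(ValueError):
    """Calibration inputs cannot yield valid thresholds."""


@dataclass(frozen=True)
class LabeledObject:
    area_px: int
    major_axis_px: float
    minor_axis_px: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise CalibrationError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if self.area_px < 1:
            raise CalibrationError(f"area_px must be >= 1, got {self.area_px}")
        if not 0 < self.minor_axis_px <= self.major_axis_px:
            raise CalibrationError(
                f"axis lengths must satisfy 0 < minor <= major, got "
                f"minor={self.minor_axis_px}, major={self.major_axis_px}"
            )

    @property
    def axis_ratio(self) -> float:
        return self.minor_axis_px / self.major_axis_px


@dataclass
class CalibrationTable:
    objects: list[LabeledObject]

    @property
    def counts(self) -> dict[str, int]:
        return {lab: sum(o.label == lab for o in self.objects) for lab in LABELS}

    def areas(self, label: str) -> np.ndarray:
        return np.array([o.area_px for o in self.objects if o.label == label], dtype=float)

    def ratios(self, label: str) -> np.ndarray:
        return np.array([o.axis_ratio for o in self.objects if o.label == label], dtype=float)


@dataclass(frozen=True)
class DetectionThresholds:
    """Derived classification boundaries used at detection time.

    ``area_min_px`` is the 16th percentile of single-fly areas (anything
    smaller is noise); ``area_single_max_px`` is the largest single-fly
    area (boundary to the multi class, and the divisor when estimating how
    many flies a merged blob holds); ``area_multi_max_px`` is the largest
    multi-fly area (anything larger is noise).  Boundary values belong to
    the fly classes: area == area_min_px or == area_single_max_px is
    single, area == area_multi_max_px is multi.
    """

    area_min_px: float
    area_single_max_px: float
    area_multi_max_px: float
    ratio_single: tuple[float, float]
    ratio_multi: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.area_min_px < self.area_single_max_px < self.area_multi_max_px:
            raise CalibrationError(
                "degenerate area thresholds: need area_min_px < area_single_max_px "
                f"< area_multi_max_px, got {self.area_min_px}, "
                f"{self.area_single_max_px}, {self.area_multi_max_px}"
            )
        for name, (lo, hi) in (("ratio_single", self.ratio_single), ("ratio_multi", self.ratio_multi)):
            if not (0 < lo <= hi <= 1):
                raise CalibrationError(f"{name} interval must lie in (0, 1], got [{lo}, {hi}]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DetectionThresholds":
        raw = json.loads(Path(path).read_text())
        raw["ratio_single"] = tuple(raw["ratio_single"])
        raw["ratio_multi"] = tuple(raw["ratio_multi"])
        return cls(**raw)


def build_calibration(labeled_csv: str | Path) -> CalibrationTable:
    """Parse a labeled-object CSV into a calibration table.

    Expects columns ``area_px, major_axis_px, minor_axis_px, label``; any
    invalid label or non-positive measurement is rejected with the row
    number.
    """
    path = Path(labeled_csv)
    df = pd.read_csv(path)
    required = {"area_px", "major_axis_px", "minor_axis_px", "label"}
    missing = required - set(df.columns)
    if missing:
        raise CalibrationError(f"calibration CSV missing column(s): {sorted(missing)}")
    if df.empty:
        raise CalibrationError(f"calibration CSV {path} has no rows; cannot derive thresholds")
    objects = []
    for idx, row in df.iterrows():
        try:
            objects.append(
                LabeledObject(
                    area_px=int(row["area_px"]),
                    major_axis_px=float(row["major_axis_px"]),
                    minor_axis_px=float(row["minor_axis_px"]),
                    label=str(row["label"]).strip(),
                )
            )
        except CalibrationError as exc:
            raise CalibrationError(f"row {idx}: {exc}") from exc
    return CalibrationTable(objects=objects)


def derive_thresholds(
    table: CalibrationTable,
    noise_percentile: float = 16.0,
    ratio_trim: float = 0.0,
) -> DetectionThresholds:
    """Derive classification thresholds from a labeled table.

    ``noise_percentile`` is the single-fly area percentile below which
    objects are called noise (linear interpolation between order
    statistics).  ``ratio_trim`` optionally trims that fraction off each
    end of the per-class axis-ratio range before taking [min, max].
    """
    singles, multis = table.areas("single"), table.areas("multi")
    if singles.size == 0 or multis.size == 0:
        raise CalibrationError(
            "need at least one 'single' and one 'multi' labeled object, "
            f"got counts {table.counts}"
        )
    if not 0 <= ratio_trim < 0.5:
        raise CalibrationError(f"ratio_trim must be in [0, 0.5), got {ratio_trim}")
    area_min = float(np.percentile(singles, noise_percentile))  # linear interpolation
    lo, hi = 100.0 * ratio_trim, 100.0 * (1 - ratio_trim)
    ratio_single = tuple(np.percentile(table.ratios("single"), [lo, hi]))
    ratio_multi = tuple(np.percentile(table.ratios("multi"), [lo, hi]))
    return DetectionThresholds(
        area_min_px=area_min,
        area_single_max_px=float(singles.max()),
        area_multi_max_px=float(multis.max()),
        ratio_single=ratio_single,
        ratio_multi=ratio_multi,
    )


def classify_object(
    area_px: float,
    minor_axis_px: float,
    major_axis_px: float,
    thresholds: DetectionThresholds,
) -> str:
    """Classify one segmented object as ``single``, ``multi`` or ``noise``.

    Area picks the candidate class (noise below area_min_px and above
    area_multi_max_px; single up to and including area_single_max_px;
    multi above); the candidate is demoted to noise if its
    minor/major-axis ratio falls outside the candidate class's calibrated
    interval.
    """
    if area_px < thresholds.area_min_px or area_px > thresholds.area_multi_max_px:
        return "noise"
    if major_axis_px <= 0:  # degenerate component (e.g. 1-px line); shapeless
        return "noise"
    ratio = minor_axis_px / major_axis_px
    if area_px <= thresholds.area_single_max_px:
        lo, hi = thresholds.ratio_single
        return "single" if lo <= ratio <= hi else "noise"
    lo, hi = thresholds.ratio_multi
    return "multi" if lo <= ratio <= hi else "noise"
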