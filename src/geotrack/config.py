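"""Run configuration and vial regions of interest.

A single JSON file configures a whole tracking run: the frame rate of the
recording, the number of flies loaded per vial, the tracker's cost of
non-assignment (CON), the background-subtraction threshold, the physical
scale, and the analytic cut-offs (displacement gate, slip/fall bounds,
climbing target heights).  All values have defaults matching a standard
30 Hz vial recording; only the ROIs are inherently per-experiment.

Coordinate convention: image convention throughout detection and tracking
(origin top-left, x rightward, y downward, 0-based pixel and frame
indices).  The analytics layer flips to vial coordinates (y up, origin at
the vial bottom) in exactly one place.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


class ConfigError(ValueError):
    """A configuration file or value violates the documented schema."""


@dataclass(frozen=True)
class ROI:
    """Half-open rectangular region of interest cropping one vial.

    ``x0, y0`` is the top-left corner in full-frame pixel coordinates; the
    rectangle covers columns ``[x0, x0 + width)`` and rows
    ``[y0, y0 + height)``.
    """

    x0: int
    y0: int
    width: int
    height: int
    vial_id: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigError(
                f"ROI width/height must be positive, got {self.width}x{self.height}"
            )
        if self.x0 < 0 or self.y0 < 0:
            raise ConfigError(f"ROI origin must be non-negative, got ({self.x0},{self.y0})")


def _default_target_heights() -> list[float]:
    # thirds / half / full height of a standard 140 mm vial
    return [140.0 / 3.0, 70.0, 140.0]


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of the tracking and analytics pipeline.

    Parameters
    ----------
    frame_rate_hz
        Video capture rate; the frame interval Δt = 1/frame_rate_hz seconds.
    n_flies
        Number of flies loaded into each vial (the tracker emits exactly
        this many trajectories per vial).
    con
        Cost of non-assignment in pixels: the padding value of the
        assignment cost matrix, i.e. the distance above which matching a
        detection to a track is rejected.
    diff_threshold
        Background-minus-frame intensity threshold (normalized units);
        differences ≤ this value are treated as background.
    displacement_gate_mm
        Frame-pair displacements at or above this are excluded from the
        speed-angle series (jumps, slips, falls, in-vial flight).
    slip_min_mm, slip_max_mm
        Single-frame-pair vertical drop bounds: drops in
        [slip_min_mm, slip_max_mm] are slips, larger drops are falls.
    px_per_mm
        Imaging scale.
    vial_height_mm
        Physical height of the climbing column covered by the ROI.
    target_heights_mm
        Heights for which climbing curves are computed.
    n_bootstrap
        Bootstrap replicates for the speed-angle correlation ratio.
    rng_seed
        Seed for every stochastic step (bottom-seeding of untracked flies,
        bootstrap resampling).
    cost_rule
        How the Kalman-prediction distance d_pred and the
        previous-coordinate distance d_prev combine into a cost-matrix
        entry: "min" (default), "mean", or "pred" (d_pred alone).
    measurement_noise_px / process_noise_px
        Kalman filter noise scales (pixel std of the centroid measurement;
        pixel/frame^2 std of the white-acceleration process noise).
    connectivity
        Pixel connectivity for blob extraction: 2 = 8-connected (default),
        1 = 4-connected.
    lost_after_frames
        Frames a track may go without a detection before it becomes
        reacquirable: beyond this, an unassigned detection anywhere in the
        vial may re-seed the track (how a fly is picked up again after a
        drop larger than CON).
    """

    frame_rate_hz: float = 30.0
    n_flies: int = 7
    con: float = 11.0
    diff_threshold: float = 0.06
    displacement_gate_mm: float = 4.0
    slip_min_mm: float = 4.5
    slip_max_mm: float = 12.0
    px_per_mm: float = 4.85
    vial_height_mm: float = 140.0
    target_heights_mm: Sequence[float] = field(default_factory=_default_target_heights)
    n_bootstrap: int = 1000
    rng_seed: int = 0
    cost_rule: str = "min"
    measurement_noise_px: float = 1.0
    process_noise_px: float = 1.0
    connectivity: int = 2
    angle_tol_deg: float = 1e-6
    lost_after_frames: int = 6
    rois: tuple[ROI, ...] = ()

    def __post_init__(self) -> None:
        positive = {
            "frame_rate_hz": self.frame_rate_hz,
            "n_flies": self.n_flies,
            "diff_threshold": self.diff_threshold,
            "displacement_gate_mm": self.displacement_gate_mm,
            "slip_min_mm": self.slip_min_mm,
            "slip_max_mm": self.slip_max_mm,
            "px_per_mm": self.px_per_mm,
            "vial_height_mm": self.vial_height_mm,
            "n_bootstrap": self.n_bootstrap,
            "measurement_noise_px": self.measurement_noise_px,
            "process_noise_px": self.process_noise_px,
        }
        for key, value in positive.items():
            if not value > 0:
                raise ConfigError(f"{key} must be positive, got {value!r}")
        if self.con < 0:
            raise ConfigError(f"con must be non-negative, got {self.con!r}")
        if not self.diff_threshold < 1:
            raise ConfigError(f"diff_threshold must lie in (0,1), got {self.diff_threshold!r}")
        if not self.slip_min_mm < self.slip_max_mm:
            raise ConfigError(
                f"slip_min_mm ({self.slip_min_mm}) must be < slip_max_mm ({self.slip_max_mm})"
            )
        for h in self.target_heights_mm:
            if not 0 < h <= self.vial_height_mm:
                raise ConfigError(
                    f"target height {h} mm outside (0, vial_height_mm={self.vial_height_mm}]"
                )
        if self.cost_rule not in ("min", "mean", "pred"):
            raise ConfigError(f"cost_rule must be 'min', 'mean' or 'pred', got {self.cost_rule!r}")
        if self.lost_after_frames < 1:
            raise ConfigError(f"lost_after_frames must be >= 1, got {self.lost_after_frames!r}")
        if self.connectivity not in (1, 2):
            raise ConfigError(f"connectivity must be 1 (4-conn) or 2 (8-conn), got {self.connectivity!r}")
        seen = set()
        for roi in self.rois:
            key = (roi.x0, roi.y0, roi.width, roi.height)
            if key in seen:
                raise ConfigError(f"duplicate ROI rectangle {key}")
            seen.add(key)

    @property
    def dt(self) -> float:
        """Frame interval in seconds (1 / frame_rate_hz)."""
        return 1.0 / self.frame_rate_hz


_CONFIG_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a run configuration from a JSON file.

    Absent keys take their defaults; unknown keys are rejected by name.
    ``rois`` is a list of ``{vial_id, x0, y0, width, height}`` objects.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config {path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a JSON object, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    """Build a RunConfig from an already-parsed JSON object."""
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = dict(raw)
    if "rois" in kwargs:
        rois = kwargs["rois"]
        if not isinstance(rois, list):
            raise ConfigError("'rois' must be a list of objects")
        parsed = []
        for i, r in enumerate(rois):
            try:
                parsed.append(ROI(**r))
            except TypeError as exc:
                raise ConfigError(f"rois[{i}]: {exc}") from exc
        kwargs["rois"] = tuple(parsed)
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:  # wrong value type slipped through
        raise ConfigError(str(exc)) from exc


def roi_template(frame_width: int, frame_height: int, n_vials: int) -> list[dict]:
    """Evenly split a frame into ``n_vials`` vertical ROI strips.

    Convenience for writing a first config by hand; prints to JSON as the
    ``rois`` entry.
    """
    if n_vials <= 0:
        raise ConfigError("n_vials must be positive")
    width = frame_width // n_vials
    if width == 0:
        raise ConfigError("frame too narrow for that many vials")
    return [
        {"vial_id": i, "x0": i * width, "y0": 0, "width": width, "height": frame_height}
        for i in range(n_vials)
    ]
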