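"""Climbing, kinematic and drop metrics from tracked coordinates.

All metrics work in vial coordinates: x in mm, y in mm measured upward
from the vial bottom (the single place where the image-convention y axis
is flipped).  From the per-frame positions this module computes:

* frame-pair displacement Δr_i, speed s_i = Δr_i/Δt, and movement angle
  θ_i = atan2(Δy_i, |Δx_i|) in degrees — folding left/right so that θ only
  reports whether motion is up (+) or down (−); θ is undefined for a
  stationary pair and pairs with Δr_i ≥ 4 mm are gated out of the
  speed-angle series as artifactual jumps, slips, falls or flight;
* climbing curves: cumulative count of flies that have first crossed a
  target height, per trial (unit steps) and averaged over trials
  (1/N_trials steps with an s.e.m. band);
* turning rate: non-zero changes of θ between consecutive defined pairs,
  per second;
* slips (4.5 mm ≤ −Δy ≤ 12 mm, about one to three body lengths) and
  falls (−Δy > 12 mm), each with the pre-drop height and the ratio of the
  drop to the maximum possible drop from that height;
* the directional-bias ratio ρ+/ρ−: Spearman correlations between speed
  and angle for upward (θ>0) vs downward (θ<0) movements, bootstrapped by
  resampling speed-angle pairs with replacement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .config import ROI, RunConfig
from .io import CoordinateMatrix


@dataclass
class Trajectory:
    """One fly's positions in vial coordinates (mm, y up from the bottom)."""

    positions_mm: np.ndarray  # (n_frames, 2)
    dt: float
    fly_id: int = 0
    trial_id: int = 0
    group: str = ""

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if self.positions_mm.ndim != 2 or self.positions_mm.shape[1] != 2:
            raise ValueError(f"positions_mm must be (n, 2), got {self.positions_mm.shape}")
        if len(self.positions_mm) < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def y_mm(self) -> np.ndarray:
        return self.positions_mm[:, 1]

    @property
    def duration_s(self) -> float:
        return (len(self.positions_mm) - 1) * self.dt


def to_physical(
    matrix: CoordinateMatrix,
    roi: ROI,
    px_per_mm: float,
    dt: float,
    trial_id: int = 0,
    group: str = "",
) -> list[Trajectory]:
    """Convert an image-convention coordinate matrix to vial coordinates.

    x_mm = x_px / px_per_mm; y_mm = (roi.height − y_px) / px_per_mm, so
    y increases upward with the origin at the vial bottom.
    """
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    out = []
    for fly in range(matrix.n_flies):
        xy = matrix.positions[fly]
        pos = np.column_stack([xy[:, 0] / px_per_mm, (roi.height - xy[:, 1]) / px_per_mm])
        out.append(Trajectory(pos, dt=dt, fly_id=fly, trial_id=trial_id, group=group))
    return out


@dataclass
class SpeedAngleSeries:
    """Frame-pair kinematics with the displacement gate applied.

    One entry per consecutive frame pair; ``theta_deg`` is NaN where the
    fly was stationary (Δr = 0) and both ``speed`` and ``theta_deg`` are
    NaN on gated pairs (Δr ≥ gate).
    """

    dr_mm: np.ndarray
    speed_mm_s: np.ndarray
    theta_deg: np.ndarray
    gated: np.ndarray  # True where Δr >= gate (excluded from s, θ)
    dt: float

    @property
    def valid_speed(self) -> np.ndarray:
        return self.speed_mm_s[~self.gated]

    @property
    def valid_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(speed, θ) over pairs that are non-gated and have defined θ."""
        ok = ~self.gated & ~np.isnan(self.theta_deg)
        return self.speed_mm_s[ok], self.theta_deg[ok]


def speed_angle(traj: Trajectory, gate_mm: float = 4.0) -> SpeedAngleSeries:
    """Compute Δr, s and θ for each consecutive frame pair.

    θ = atan2(Δy, |Δx|) in degrees, in (−90, 90]: straight up is +90,
    straight down −90, and leftward motion is indistinguishable from
    rightward.  Pairs with Δr ≥ gate_mm (default 4 mm) are excluded from
    the speed-angle data, which caps usable speeds near 120 mm/s at 30 Hz.
    """
    delta = np.diff(traj.positions_mm, axis=0)
    dr = np.linalg.norm(delta, axis=1)
    speed = dr / traj.dt
    with np.errstate(invalid="ignore"):
        theta = np.degrees(np.arctan2(delta[:, 1], np.abs(delta[:, 0])))
    theta[dr == 0] = np.nan  # stationary pair: direction undefined
    gated = dr >= gate_mm
    speed = np.where(gated, np.nan, speed)
    theta = np.where(gated, np.nan, theta)
    return SpeedAngleSeries(dr_mm=dr, speed_mm_s=speed, theta_deg=theta, gated=gated, dt=traj.dt)


def turning_rate(series: SpeedAngleSeries, angle_tol_deg: float = 1e-6) -> float:
    """Turns per second: non-zero θ changes between consecutive defined pairs.

    Only consecutive pairs where θ is defined on both sides contribute; an
    undefined-θ pair breaks the chain.  The elapsed time is the full
    trajectory duration.
    """
    theta = series.theta_deg
    both = ~np.isnan(theta[:-1]) & ~np.isnan(theta[1:])
    turns = int(np.sum(np.abs(theta[1:] - theta[:-1])[both] > angle_tol_deg))
    elapsed = len(theta) * series.dt
    return turns / elapsed


@dataclass
class ClimbingCurve:
    """Cumulative first-crossing counts for one target height.

    ``times`` is the sorted union of crossing times across trials;
    ``mean_counts`` the across-trial average cumulative count (step
    1/N_trials per fly) and ``sem_counts`` the standard error of the mean
    at each step time.  ``per_trial`` holds each trial's own staircase as
    (times, counts) with unit steps.
    """

    target_height_mm: float
    times: np.ndarray
    mean_counts: np.ndarray
    sem_counts: np.ndarray
    per_trial: list[tuple[np.ndarray, np.ndarray]]
    n_trials: int
    n_flies: int


def first_crossing_time(traj: Trajectory, target_height_mm: float) -> float | None:
    """Time of the first frame strictly above the target, or None.

    A fly is counted at its first crossing even if it later drops back
    below the target.
    """
    above = np.nonzero(traj.y_mm > target_height_mm)[0]
    if above.size == 0:
        return None
    return float(above[0] * traj.dt)


def climbing_curve(
    trials: list[list[Trajectory]],
    target_height_mm: float,
    vial_height_mm: float = 140.0,
) -> ClimbingCurve:
    """Build per-trial and across-trial climbing curves for one height."""
    if target_height_mm > vial_height_mm:
        raise ValueError(
            f"target {target_height_mm} mm exceeds vial height {vial_height_mm} mm"
        )
    if not trials or any(len(t) == 0 for t in trials):
        raise ValueError("every trial must contain at least one trajectory")
    n_flies = len(trials[0])
    per_trial = []
    all_times = []
    for trajs in trials:
        crossings = sorted(
            t for t in (first_crossing_time(tr, target_height_mm) for tr in trajs) if t is not None
        )
        times = np.array(crossings)
        counts = np.arange(1, len(crossings) + 1, dtype=float)
        per_trial.append((times, counts))
        all_times.extend(crossings)
    union = np.unique(np.array(all_times)) if all_times else np.array([])
    n_trials = len(trials)
    at_union = np.empty((n_trials, len(union)))
    for i, (times, counts) in enumerate(per_trial):
        # trial staircase evaluated at each union time (right-continuous)
        at_union[i] = np.searchsorted(times, union, side="right")
    mean = at_union.mean(axis=0) if len(union) else np.array([])
    sem = (
        at_union.std(axis=0, ddof=1) / np.sqrt(n_trials)
        if n_trials > 1 and len(union)
        else np.zeros(len(union))
    )
    return ClimbingCurve(
        target_height_mm=target_height_mm,
        times=union,
        mean_counts=mean,
        sem_counts=sem,
        per_trial=per_trial,
        n_trials=n_trials,
        n_flies=n_flies,
    )


@dataclass(frozen=True)
class DropEvent:
    """A slip or fall: a large single-frame-pair loss of height."""

    kind: str  # "slip" or "fall"
    frame_index: int  # index of the pre-drop frame
    pre_drop_height_mm: float
    drop_mm: float
    ratio: float  # drop / maximum possible drop (the pre-drop height)


def detect_drops(
    traj: Trajectory, slip_min_mm: float = 4.5, slip_max_mm: float = 12.0
) -> list[DropEvent]:
    """Find slips (slip_min ≤ −Δy ≤ slip_max) and falls (−Δy > slip_max).

    The ratio compares the drop with the maximum possible drop from the
    pre-drop height (ratio 1 means the fly hit the vial bottom).
    """
    y = traj.y_mm
    drops = -np.diff(y)
    events = []
    for i in np.nonzero(drops >= slip_min_mm)[0]:
        drop = float(drops[i])
        pre = float(y[i])
        kind = "slip" if drop <= slip_max_mm else "fall"
        ratio = min(drop / pre, 1.0) if pre > 0 else 1.0
        events.append(
            DropEvent(kind=kind, frame_index=int(i), pre_drop_height_mm=pre, drop_mm=drop, ratio=ratio)
        )
    return events


@dataclass
class RhoRatioEstimate:
    """Bootstrapped directional-bias ratio ρ+/ρ− of speed-angle Spearman correlations."""

    rho_plus: float
    rho_minus: float
    ratio_mean: float
    ratio_sd: float
    n_sample: int
    n_replicates: int
    n_discarded: int


def _split_spearman(speed: np.ndarray, theta: np.ndarray) -> tuple[float, float]:
    """Spearman ρ on the θ>0 and θ<0 strata; NaN for a stratum under 3 pairs."""
    import warnings

    out = []
    for mask in (theta > 0, theta < 0):
        if mask.sum() < 3:
            out.append(np.nan)
        else:
            with warnings.catch_warnings():
                # a constant stratum yields NaN, which the caller discards
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                out.append(float(stats.spearmanr(speed[mask], theta[mask]).statistic))
    return out[0], out[1]


def bootstrap_rho_ratio(
    speed: np.ndarray,
    theta: np.ndarray,
    n_replicates: int = 1000,
    seed: int | None = None,
) -> RhoRatioEstimate:
    """Bootstrap the ratio ρ+/ρ− of speed-angle Spearman correlations.

    Each replicate resamples N_sample = len(data) speed-angle pairs with
    replacement, splits them by the sign of θ, and takes the ratio of the
    two stratum Spearman coefficients.  Replicates where a stratum has
    fewer than 3 pairs, a coefficient is undefined, or ρ− = 0 are
    discarded (and counted).  The mean and standard deviation of the
    surviving replicate ratios are the reported estimate and its error.
    """
    speed = np.asarray(speed, dtype=float)
    theta = np.asarray(theta, dtype=float)
    ok = ~np.isnan(speed) & ~np.isnan(theta)
    speed, theta = speed[ok], theta[ok]
    n = len(speed)
    if (theta > 0).sum() < 3 or (theta < 0).sum() < 3:
        raise ValueError("each θ-sign stratum needs at least 3 pairs in the full data")
    rho_plus, rho_minus = _split_spearman(speed, theta)
    rng = np.random.default_rng(seed)
    ratios = []
    discarded = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        rp, rm = _split_spearman(speed[idx], theta[idx])
        if np.isnan(rp) or np.isnan(rm) or rm == 0:
            discarded += 1
            continue
        ratios.append(rp / rm)
    ratios = np.array(ratios)
    if ratios.size == 0:
        raise ValueError("all bootstrap replicates were degenerate")
    return RhoRatioEstimate(
        rho_plus=rho_plus,
        rho_minus=rho_minus,
        ratio_mean=float(ratios.mean()),
        ratio_sd=float(ratios.std(ddof=0)),
        n_sample=n,
        n_replicates=n_replicates,
        n_discarded=discarded,
    )


@dataclass
class FlySummary:
    """Per-fly analytics (speeds mm/s, angles degrees, distances mm)."""

    ave_speed: float
    ave_angle: float
    distance_traveled: float
    turn_rate: float
    n_slips: int
    n_falls: int
    drops: list[DropEvent]
    spd_angle: np.ndarray  # (n, 2) valid (speed, θ) pairs


@dataclass
class GroupSummary:
    """Nested per-group → per-fly analytics, MATLAB-structure style.

    ``resolve("Group(1).Fly_no(2).AveSpeed")`` mirrors the 1-based access
    pattern of the original analysis structure.
    """

    names: list[str]
    groups: list[dict] = field(default_factory=list)

    def resolve(self, path: str):
        """Resolve a 1-based ``Group(i).Fly_no(j).Field``-style query."""
        import re

        m = re.fullmatch(r"Group\((\d+)\)\.(\w+)(?:\((\d+)\)\.(\w+))?", path.strip())
        if not m:
            raise KeyError(f"cannot parse query path {path!r}")
        g = self.groups[int(m.group(1)) - 1]
        if m.group(3) is None:
            key = {"Names": "name", "ClimbCurves": "climb_curves"}.get(m.group(2), m.group(2))
            return g[key]
        if m.group(2) != "Fly_no":
            raise KeyError(f"unknown per-group index field {m.group(2)!r}")
        fly = g["flies"][int(m.group(3)) - 1]
        key = {
            "AveSpeed": "ave_speed",
            "AveAngle": "ave_angle",
            "SpdAngle": "spd_angle",
            "Drops": "drops",
            "TurnRate": "turn_rate",
            "DistanceTraveled": "distance_traveled",
        }.get(m.group(4))
        if key is None:
            raise KeyError(f"unknown per-fly field {m.group(4)!r}")
        return getattr(fly, key)


def summarize_fly(traj: Trajectory, config: RunConfig) -> FlySummary:
    """All per-fly metrics for one trajectory."""
    series = speed_angle(traj, gate_mm=config.displacement_gate_mm)
    speeds = series.valid_speed
    s, th = series.valid_pairs
    drops = detect_drops(traj, config.slip_min_mm, config.slip_max_mm)
    ave_speed = float(np.nanmean(speeds)) if speeds.size else 0.0
    ave_angle = float(th.mean()) if th.size else float("nan")
    return FlySummary(
        ave_speed=ave_speed,
        ave_angle=ave_angle,
        distance_traveled=ave_speed * traj.duration_s,
        turn_rate=turning_rate(series, config.angle_tol_deg),
        n_slips=sum(d.kind == "slip" for d in drops),
        n_falls=sum(d.kind == "fall" for d in drops),
        drops=drops,
        spd_angle=np.column_stack([s, th]) if s.size else np.empty((0, 2)),
    )


def summarize(
    groups: dict[str, list[list[Trajectory]]],
    config: RunConfig,
) -> GroupSummary:
    """Summarize named groups of trials into the nested analytics structure.

    ``groups`` maps a group name to its trials, each a list of per-fly
    trajectories.  Per fly (pooled over trials in input order):
    average gated speed and defined-angle average, distance traveled,
    turn rate, drops; per group: climbing curves at the configured target
    heights.
    """
    summary = GroupSummary(names=list(groups))
    for name, trials in groups.items():
        if not trials:
            raise ValueError(f"group {name!r} has no trials")
        flies = [summarize_fly(traj, config) for trajs in trials for traj in trajs]
        curves = {
            h: climbing_curve(trials, h, config.vial_height_mm)
            for h in config.target_heights_mm
        }
        summary.groups.append({"name": name, "flies": flies, "climb_curves": curves})
    return summary


def write_summary_json(summary: GroupSummary, path: str | Path) -> None:
    """Serialize a GroupSummary to JSON (arrays as lists, curves flattened)."""

    def fly_dict(f: FlySummary) -> dict:
        d = {
            "ave_speed": f.ave_speed,
            "ave_angle": f.ave_angle,
            "distance_traveled": f.distance_traveled,
            "turn_rate": f.turn_rate,
            "n_slips": f.n_slips,
            "n_falls": f.n_falls,
            "drops": [asdict(x) for x in f.drops],
            "spd_angle": f.spd_angle.tolist(),
        }
        return d

    payload = {
        "groups": [
            {
                "name": g["name"],
                "flies": [fly_dict(f) for f in g["flies"]],
                "climb_curves": {
                    str(h): {
                        "times": c.times.tolist(),
                        "mean_counts": c.mean_counts.tolist(),
                        "sem_counts": c.sem_counts.tolist(),
                        "n_trials": c.n_trials,
                    }
                    for h, c in g["climb_curves"].items()
                },
            }
            for g in summary.groups
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2))
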