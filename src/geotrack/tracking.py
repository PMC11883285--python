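"""Detection-to-track association and trajectory assembly.

Each fly is carried by a constant-velocity Kalman filter whose state is
(x, y, vx, vy) in pixels and pixels/frame.  Every frame, each live track
offers two distance estimates to every detection: d_pred, the Euclidean
distance from the Kalman prediction, and d_prev, the distance from the
track's last known coordinates.  The two combine (by default the minimum;
fly motion is erratic enough that the raw prediction alone is
unreliable) into a cost-matrix entry.  The matrix is padded to square
with the cost of non-assignment (CON) so that the Hungarian solver can
leave tracks unmatched (a lost or stationary fly) and detections
unmatched (a new or re-appearing fly); with uniform padding an isolated
track-detection pair is matched exactly when its distance is below CON.

Track management follows the vial's known occupancy: new tracks are
created from unassigned detections only while fewer tracks than flies
exist (surplus detections are discarded farthest-first); unassigned
tracks coast on their last known coordinates; and any fly never seen by
the end of the video is finalized as a stationary track at a random spot
at the vial bottom, where undetected flies overwhelmingly sit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .calibration import DetectionThresholds
from .config import RunConfig
from .detection import compute_background, detect_frame, expand_detections
from .io import CoordinateMatrix, FrameStack

# fraction of the ROI height, measured up from the bottom edge, in which
# never-detected flies are seeded
_BOTTOM_BAND = 0.05


class KalmanCV:
    """Constant-velocity Kalman filter for one fly centroid.

    State (x, y, vx, vy); one time step = one frame.  Process noise is a
    discrete white-acceleration model with std ``process_noise`` px/frame²;
    the measurement is the detection centroid with isotropic std
    ``measurement_noise`` px.  The initial velocity is zero with a large
    variance, so early predictions stay near the first detection until
    motion is observed.
    """

    F = np.array(
        [[1.0, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]]
    )
    H = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])

    def __init__(
        self,
        x0: float,
        y0: float,
        measurement_noise: float = 1.0,
        process_noise: float = 1.0,
        init_velocity_std: float = 100.0,
    ) -> None:
        self.x = np.array([x0, y0, 0.0, 0.0])
        r2 = measurement_noise**2
        self.P = np.diag([r2, r2, init_velocity_std**2, init_velocity_std**2])
        q2 = process_noise**2
        g = np.array([[0.5, 0], [0, 0.5], [1, 0], [0, 1]])  # accel -> state
        self.Q = q2 * (g @ g.T)
        self.R = r2 * np.eye(2)

    def predict(self) -> np.ndarray:
        """Time update; returns the predicted (x, y)."""
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q
        return self.x[:2].copy()

    def update(self, z: np.ndarray) -> None:
        """Measurement update with a detection centroid (x, y)."""
        z = np.asarray(z, dtype=float)
        y = z - self.H @ self.x
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.P = (np.eye(4) - K @ self.H) @ self.P


@dataclass
class Track:
    """One fly's trajectory under construction."""

    track_id: int
    kf: KalmanCV
    last_known: np.ndarray  # (x_px, y_px) of most recent history entry
    start_frame: int
    history: list[np.ndarray] = field(default_factory=list)
    observed: list[bool] = field(default_factory=list)
    frames_invisible: int = 0
    predicted: np.ndarray | None = None  # current-frame Kalman prediction

    @property
    def age_frames(self) -> int:
        return len(self.history)


@dataclass
class Assignment:
    """Partition of tracks and detections produced by the solver."""

    pairs: list[tuple[int, int]]  # (track index, detection index)
    unassigned_tracks: list[int]
    unassigned_detections: list[int]


def predict_tracks(tracks: list[Track]) -> np.ndarray:
    """Run the Kalman time update on every track; (T, 2) predictions."""
    preds = np.empty((len(tracks), 2))
    for i, tr in enumerate(tracks):
        tr.predicted = tr.kf.predict()
        preds[i] = tr.predicted
    return preds


def build_cost_matrix(
    tracks: list[Track],
    detections: np.ndarray,
    con: float,
    rule: str = "min",
) -> np.ndarray:
    """Build the padded square assignment cost matrix.

    The real T×D block combines d_pred (detection to Kalman prediction)
    and d_prev (detection to last known coordinates) according to
    ``rule`` ("min", "mean" or "pred").  The matrix is padded to side
    T + D with ``con`` everywhere outside the real block, so phantom
    rows/columns price non-assignment.
    """
    if con < 0:
        raise ValueError(f"con must be non-negative, got {con}")
    T, D = len(tracks), len(detections)
    padded = np.full((T + D, T + D), float(con))
    if T and D:
        det = np.asarray(detections, dtype=float)
        pred = np.stack([tr.predicted if tr.predicted is not None else tr.last_known for tr in tracks])
        prev = np.stack([tr.last_known for tr in tracks])
        d_pred = np.linalg.norm(pred[:, None, :] - det[None, :, :], axis=2)
        d_prev = np.linalg.norm(prev[:, None, :] - det[None, :, :], axis=2)
        if rule == "min":
            padded[:T, :D] = np.minimum(d_pred, d_prev)
        elif rule == "mean":
            padded[:T, :D] = 0.5 * (d_pred + d_prev)
        elif rule == "pred":
            padded[:T, :D] = d_pred
        else:
            raise ValueError(f"unknown cost rule {rule!r}")
    return padded


def assign(cost: np.ndarray, n_tracks: int, n_detections: int) -> Assignment:
    """Minimum-cost perfect matching on the padded matrix (Hungarian).

    A track matched into the phantom columns is unassigned; a detection
    matched from the phantom rows is unassigned.
    """
    cost = np.asarray(cost, dtype=float)
    if not np.isfinite(cost).all():
        raise ValueError("cost matrix contains non-finite entries")
    side = n_tracks + n_detections
    if cost.shape != (side, side):
        raise ValueError(f"expected padded square matrix of side {side}, got {cost.shape}")
    rows, cols = linear_sum_assignment(cost)
    pairs, un_tracks, un_dets = [], [], []
    for r, c in zip(rows, cols):
        if r < n_tracks and c < n_detections:
            pairs.append((r, c))
        elif r < n_tracks:
            un_tracks.append(r)
        elif c < n_detections:
            un_dets.append(c)
    return Assignment(pairs=pairs, unassigned_tracks=un_tracks, unassigned_detections=un_dets)


def update_tracks(
    tracks: list[Track],
    detections: np.ndarray,
    assignment: Assignment,
    n_flies: int,
    frame_index: int,
    config: RunConfig,
) -> list[Track]:
    """Apply one frame's assignment to the track list (in place).

    Assigned tracks take the detection as a Kalman measurement and record
    it.  Unassigned detections first found new tracks while the track
    count is below the vial's fly count (surplus discarded in decreasing
    order of distance to the nearest unassigned track's previous
    coordinates); any still left may then *reacquire* a track that has
    been invisible longer than ``config.lost_after_frames`` — that track's
    Kalman filter restarts at the detection, keeping the row identity, and
    the recorded coordinates show the drop that lost the fly as one large
    frame-pair displacement.  Remaining unassigned tracks coast on (and
    are measured at) their last known coordinates.
    """
    det = np.asarray(detections, dtype=float).reshape(-1, 2)
    seen = [i for i, _ in assignment.pairs] + assignment.unassigned_tracks
    if sorted(seen) != list(range(len(tracks))):
        raise ValueError("assignment does not partition the track list")

    for ti, di in assignment.pairs:
        tr = tracks[ti]
        z = det[di]
        tr.kf.update(z)
        tr.last_known = z.copy()
        tr.history.append(z.copy())
        tr.observed.append(True)
        tr.frames_invisible = 0

    new_dets = list(assignment.unassigned_detections)
    lost_prev = [tracks[ti].last_known for ti in assignment.unassigned_tracks]
    room = n_flies - len(tracks)
    if len(new_dets) > room:
        reacquirable = [
            ti
            for ti in assignment.unassigned_tracks
            if tracks[ti].frames_invisible >= config.lost_after_frames
        ]
        keep = max(room, 0) + len(reacquirable)
        if len(new_dets) > keep:
            if lost_prev:
                anchor = np.stack(lost_prev)
                dist_to_lost = [
                    float(np.linalg.norm(anchor - det[di], axis=1).min()) for di in new_dets
                ]
            else:
                dist_to_lost = [float("inf")] * len(new_dets)
            # keep the detections closest to an unassigned track; drop
            # farthest first, ties broken by detection index ascending
            order = sorted(range(len(new_dets)), key=lambda k: (dist_to_lost[k], new_dets[k]))
            new_dets = sorted(new_dets[k] for k in order[:keep])

    next_id = max((tr.track_id for tr in tracks), default=-1) + 1
    founding = new_dets[: max(room, 0)]
    leftover = new_dets[max(room, 0) :]
    for di in founding:
        z = det[di]
        tr = Track(
            track_id=next_id,
            kf=KalmanCV(
                z[0],
                z[1],
                measurement_noise=config.measurement_noise_px,
                process_noise=config.process_noise_px,
            ),
            last_known=z.copy(),
            start_frame=frame_index,
        )
        tr.history.append(z.copy())
        tr.observed.append(True)
        tracks.append(tr)
        next_id += 1

    reacquired: set[int] = set()
    if leftover:
        stale = [
            ti
            for ti in assignment.unassigned_tracks
            if tracks[ti].frames_invisible >= config.lost_after_frames
        ]
        if stale:
            # pair long-lost tracks with leftover detections at minimum
            # total distance; each lost track picks up at most one fly
            cost = np.array(
                [[np.linalg.norm(tracks[ti].last_known - det[di]) for di in leftover] for ti in stale]
            )
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                ti, di = stale[r], leftover[c]
                tr = tracks[ti]
                z = det[di]
                tr.kf = KalmanCV(
                    z[0],
                    z[1],
                    measurement_noise=config.measurement_noise_px,
                    process_noise=config.process_noise_px,
                )
                tr.last_known = z.copy()
                tr.history.append(z.copy())
                tr.observed.append(True)
                tr.frames_invisible = 0
                reacquired.add(ti)

    for ti in assignment.unassigned_tracks:
        if ti in reacquired:
            continue
        tr = tracks[ti]
        # the lost-and-found rule: the recorded coordinates hold at the
        # last known position, while the Kalman filter keeps extrapolating
        # so a moving fly can be reconnected via d_pred and a stationary
        # one via d_prev
        tr.history.append(tr.last_known.copy())
        tr.observed.append(False)
        tr.frames_invisible += 1
    return tracks


def track_points(
    points_per_frame: list[np.ndarray],
    config: RunConfig,
    roi_shape: tuple[int, int],
) -> CoordinateMatrix:
    """Associate pre-computed per-frame detection points into trajectories.

    ``points_per_frame`` holds an (n_i, 2) array of individual-fly points
    for each frame (multi-fly blobs already expanded).  Finalization
    backfills each track's pre-birth frames with its first known position
    and seeds any never-created fly as a stationary track at a random
    coordinate at the bottom of the ROI (reproducible via
    ``config.rng_seed``).  Exactly ``config.n_flies`` rows are returned.
    """
    n_frames = len(points_per_frame)
    if n_frames < 1:
        raise ValueError("need at least one frame")
    tracks: list[Track] = []
    for f, pts in enumerate(points_per_frame):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        predict_tracks(tracks)
        cost = build_cost_matrix(tracks, pts, config.con, config.cost_rule)
        assignment = assign(cost, len(tracks), len(pts))
        update_tracks(tracks, pts, assignment, config.n_flies, f, config)

    height, width = roi_shape
    rng = np.random.default_rng(config.rng_seed)
    positions = np.empty((config.n_flies, n_frames, 2))
    observed = np.zeros((config.n_flies, n_frames), dtype=bool)
    tracks = sorted(tracks, key=lambda tr: tr.track_id)
    for row, tr in enumerate(tracks):
        hist = np.stack(tr.history)
        positions[row, tr.start_frame :] = hist
        positions[row, : tr.start_frame] = hist[0]  # pre-birth backfill
        observed[row, tr.start_frame :] = tr.observed
    for row in range(len(tracks), config.n_flies):
        # fly never detected: park it at a random spot at the vial bottom
        x = rng.uniform(0, width)
        y = rng.uniform(height * (1 - _BOTTOM_BAND), height)
        positions[row] = (x, y)
    return CoordinateMatrix(
        positions=positions,
        observed=observed,
        metadata={"n_tracks_created": len(tracks)},
    )


def track_video(
    stack: FrameStack,
    thresholds: DetectionThresholds,
    config: RunConfig,
) -> CoordinateMatrix:
    """Full tracking pipeline for one vial-cropped video.

    Median background → per-frame detection → Kalman/Hungarian
    association → finalized coordinate matrix with exactly
    ``config.n_flies`` rows.
    """
    if config.n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    background = compute_background(stack)
    points = [
        expand_detections(
            detect_frame(
                frame,
                background,
                thresholds,
                diff_threshold=config.diff_threshold,
                connectivity=config.connectivity,
            )
        )
        for frame in stack.frames
    ]
    matrix = track_points(points, config, stack.shape)
    matrix.metadata["frame_rate_hz"] = stack.frame_rate_hz
    return matrix
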