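"""StrongSORT-style multi-object tracking for individually identified animals.

The tracker follows the DeepSORT lineage: a constant-velocity Kalman
filter per track on the measurement vector (cx, cy, a, h) — box center,
aspect ratio, height — with two departures that define the method:

* **NSA noise adaptation** — the measurement-noise covariance used in the
  update is scaled by the detection confidence, ``R~ = (1 - c) R``, so
  confident detections correct the state more strongly.
* **EMA appearance state** — each track keeps an exponentially weighted
  running embedding, ``e_t = alpha * e_{t-1} + (1 - alpha) * f_t`` with
  momentum ``alpha`` (default 0.9), renormalized to unit length.

Association minimizes a convex combination of appearance (cosine) and
motion (squared Mahalanobis) costs, ``C = lambda * A_a + (1 - lambda) *
A_m`` with ``lambda = 0.98``, over a single global assignment; motion
distances beyond a chi-square gate are infeasible. Camera motion
compensation is the identity transform: the cameras are fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

#: chi-square 95% quantile, 4 degrees of freedom (measurement dimension)
CHI2_GATE_4DOF = 9.4877

#: sentinel marking gated-out (infeasible) cost entries
INFEASIBLE = np.inf


class TrackingError(ValueError):
    pass


class TrackStatus(Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass(frozen=True)
class Detection:
    """One observed box in one frame.

    ``box`` is (x, y, w, h) — top-left corner plus size, pixels.
    ``class_scores`` is a vector over identity labels; ``embedding`` is a
    unit-norm appearance vector from an external re-identification model.
    """

    frame: int
    box: tuple[float, float, float, float]
    confidence: float
    class_scores: np.ndarray
    embedding: np.ndarray

    def __post_init__(self) -> None:
        x, y, w, h = self.box
        if w <= 0 or h <= 0:
            raise TrackingError(f"box must have positive size, got w={w}, h={h}")
        if not 0.0 <= self.confidence <= 1.0:
            raise TrackingError(f"confidence must be in [0, 1], got {self.confidence}")
        emb = np.asarray(self.embedding, dtype=float)
        n = np.linalg.norm(emb)
        if abs(n - 1.0) > 1e-6:
            raise TrackingError(f"embedding must be unit-norm, got ||e||={n:.8f}")
        object.__setattr__(self, "embedding", emb)
        object.__setattr__(
            self, "class_scores", np.asarray(self.class_scores, dtype=float)
        )

    def to_measurement(self) -> np.ndarray:
        """Box as the Kalman measurement (cx, cy, a, h)."""
        x, y, w, h = self.box
        return np.array([x + w / 2.0, y + h / 2.0, w / h, h])

    @property
    def bottom_center(self) -> tuple[float, float]:
        x, y, w, h = self.box
        return (x + w / 2.0, y + h)

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.box
        return (x + w / 2.0, y + h / 2.0)


@dataclass
class CostConfig:
    """Association weights and thresholds.

    lambda_weight
        Weight of the appearance cost in the combined cost (default 0.98;
        motion contributes the remaining 0.02).
    gate_threshold
        Chi-square gate on the squared Mahalanobis motion distance.
    max_cost
        Combined-cost ceiling; dearer matches are rejected.
    """

    lambda_weight: float = 0.98
    gate_threshold: float = CHI2_GATE_4DOF
    max_cost: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise TrackingError("lambda_weight must be in [0, 1]")


# ---------------------------------------------------------------------------
# Kalman primitives (pure functions; any state/measurement dimension)
# ---------------------------------------------------------------------------

def kf_predict(
    mean: np.ndarray, cov: np.ndarray, F: np.ndarray, Q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standard Kalman predict: x <- F x, P <- F P F' + Q."""
    mean = F @ mean
    cov = F @ cov @ F.T + Q
    return mean, 0.5 * (cov + cov.T)


def kf_update(
    mean: np.ndarray,
    cov: np.ndarray,
    z: np.ndarray,
    H: np.ndarray,
    R: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard Kalman measurement update with gain K = P H' S^-1.

    Uses the Joseph-form covariance update, which preserves symmetry and
    positive semidefiniteness even with a near-zero R (the NSA limit at
    confidence 1).
    """
    if not np.all(np.isfinite(z)):
        raise TrackingError("invalid measurement: non-finite values")
    S = H @ cov @ H.T + R
    K = np.linalg.solve(S.T, H @ cov.T).T
    innovation = z - H @ mean
    mean = mean + K @ innovation
    I_KH = np.eye(cov.shape[0]) - K @ H
    cov = I_KH @ cov @ I_KH.T + K @ R @ K.T
    return mean, 0.5 * (cov + cov.T)


def innovation_covariance(cov: np.ndarray, H: np.ndarray, R: np.ndarray) -> np.ndarray:
    return H @ cov @ H.T + R


# ---------------------------------------------------------------------------
# Constant-velocity box motion model
# ---------------------------------------------------------------------------

class MotionModel:
    """Constant-velocity model on (cx, cy, a, h) + velocities (8-dim state).

    ``R`` is the preset constant measurement-noise covariance; the NSA
    update scales it per detection. A floor ``eps_r * R`` keeps the scaled
    covariance nonsingular at confidence 1.
    """

    NDIM = 4

    def __init__(
        self,
        std_meas_pos: float = 2.0,
        std_meas_aspect: float = 0.05,
        std_q_pos: float = 5.0,
        std_q_vel: float = 3.0,
        std_q_aspect: float = 5e-3,
        std_q_vel_aspect: float = 1e-4,
        eps_r: float = 1e-6,
    ):
        n = self.NDIM
        self.F = np.eye(2 * n)
        self.F[:n, n:] = np.eye(n)  # dt = 1 tracker step
        self.H = np.eye(n, 2 * n)
        self.R = np.diag(
            [std_meas_pos**2, std_meas_pos**2, std_meas_aspect**2, std_meas_pos**2]
        )
        # process noise sized for a maneuvering target between sampled
        # frames (the detector runs every few video frames)
        self.Q = np.diag(
            [std_q_pos**2, std_q_pos**2, std_q_aspect**2, std_q_pos**2]
            + [std_q_vel**2, std_q_vel**2, std_q_vel_aspect**2, std_q_vel**2]
        )
        self.eps_r = eps_r
        self._init_cov = np.diag(
            [4 * std_meas_pos**2, 4 * std_meas_pos**2, 4 * std_meas_aspect**2, 4 * std_meas_pos**2]
            + [25 * std_q_vel**2, 25 * std_q_vel**2, 1e-2, 25 * std_q_vel**2]
        )

    def initiate(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean = np.zeros(2 * self.NDIM)
        mean[: self.NDIM] = z
        return mean, self._init_cov.copy()

    def nsa_noise(self, confidence: float) -> np.ndarray:
        """Eq.-style adaptive noise: R~ = (1 - c) R, floored at eps_r * R."""
        scale = 1.0 - confidence
        if scale < self.eps_r:
            logger.debug(
                "NSA scale %.3g below floor %.3g; flooring", scale, self.eps_r
            )
            scale = self.eps_r
        return scale * self.R


@dataclass
class KalmanState:
    mean: np.ndarray
    covariance: np.ndarray


@dataclass
class Track:
    """One tracked individual: motion state, appearance state, lifecycle."""

    track_id: int
    kalman: KalmanState
    appearance: np.ndarray
    alpha: float = 0.9
    status: TrackStatus = TrackStatus.TENTATIVE
    hits: int = 1
    time_since_update: int = 0
    identity_votes: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def identity(self) -> int:
        """Pooled identity: argmax of accumulated votes (lowest index wins ties)."""
        if self.identity_votes.size == 0 or self.identity_votes.sum() == 0:
            return -1
        return int(np.argmax(self.identity_votes))

    def predicted_measurement(self, H: np.ndarray) -> np.ndarray:
        return H @ self.kalman.mean

    def to_box(self) -> tuple[float, float, float, float]:
        cx, cy, a, h = self.kalman.mean[:4]
        w = a * h
        return (cx - w / 2.0, cy - h / 2.0, w, h)


# ---------------------------------------------------------------------------
# Track-level operations
# ---------------------------------------------------------------------------

def predict(track: Track, model: MotionModel) -> Track:
    """Propagate the track one frame; increments time_since_update."""
    if track.status is TrackStatus.DELETED:
        raise TrackingError("cannot predict a deleted track")
    mean, cov = kf_predict(track.kalman.mean, track.kalman.covariance, model.F, model.Q)
    track.kalman = KalmanState(mean, cov)
    track.time_since_update += 1
    return track

def nsa_update(track: Track, det: Detection, model: MotionModel) -> Track:
    """Kalman measurement update with confidence-scaled noise R~ = (1-c)R."""
    R_nsa = model.nsa_noise(det.confidence)
    mean, cov = kf_update(
        track.kalman.mean, track.kalman.covariance, det.to_measurement(), model.H, R_nsa
    )
    track.kalman = KalmanState(mean, cov)
    track.hits += 1
    track.time_since_update = 0
    return track

def ema_update(track: Track, det: Detection) -> Track:
    """Exponential moving average of the appearance embedding, renormalized."""
    if track.appearance.shape != det.embedding.shape:
        raise TrackingError("embedding dimension mismatch")
    mixed = track.alpha * track.appearance + (1.0 - track.alpha) * det.embedding
    norm = np.linalg.norm(mixed)
    if norm < 1e-12:
        logger.warning(
            "track %d: EMA produced a zero-norm embedding (antipodal inputs); "
            "keeping previous appearance",
            track.track_id,
        )
        return track
    track.appearance = mixed / norm
    return track


def appearance_cost(tracks: Sequence[Track], dets: Sequence[Detection]) -> np.ndarray:
    """Cosine-distance matrix A_a[i, j] = 1 - <e_i, f_j>, clipped to [0, 2]."""
    if not tracks or not dets:
        return np.zeros((len(tracks), len(dets)))
    E = np.stack([t.appearance for t in tracks])
    F_ = np.stack([d.embedding for d in dets])
    if E.shape[1] != F_.shape[1]:
        raise TrackingError("embedding dimension mismatch between tracks and detections")
    return np.clip(1.0 - E @ F_.T, 0.0, 2.0)


def motion_cost(
    tracks: Sequence[Track],
    dets: Sequence[Detection],
    model: MotionModel,
    gate_threshold: float = CHI2_GATE_4DOF,
) -> np.ndarray:
    """Squared Mahalanobis distance in measurement space, chi-square gated.

    Entries exceeding ``gate_threshold`` are set to ``INFEASIBLE`` and
    excluded from assignment. A singular innovation covariance is
    regularized by adding 1e-9 * I with a logged warning.
    """
    A = np.zeros((len(tracks), len(dets)))
    if not tracks or not dets:
        return A
    Z = np.stack([d.to_measurement() for d in dets])
    for i, t in enumerate(tracks):
        S = innovation_covariance(t.kalman.covariance, model.H, model.R)
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            logger.warning("singular innovation covariance; regularizing with 1e-9 I")
            L = np.linalg.cholesky(S + 1e-9 * np.eye(S.shape[0]))
        diff = Z - t.predicted_measurement(model.H)  # (n_dets, 4)
        sol = np.linalg.solve(L, diff.T)
        A[i] = np.sum(sol**2, axis=0)
    A[A > gate_threshold] = INFEASIBLE
    return A


def combined_cost(A_a: np.ndarray, A_m: np.ndarray, cfg: CostConfig) -> np.ndarray:
    """C = lambda * A_a + (1 - lambda) * A_m; infeasible entries stay infeasible."""
    if A_a.shape != A_m.shape:
        raise TrackingError(f"cost shape mismatch: {A_a.shape} vs {A_m.shape}")
    lam = cfg.lambda_weight
    with np.errstate(invalid="ignore"):
        C = lam * A_a + (1.0 - lam) * A_m
    C[~np.isfinite(A_m)] = INFEASIBLE
    C[~np.isfinite(A_a)] = INFEASIBLE
    return C


def associate(
    C: np.ndarray, max_cost: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Globally optimal assignment over feasible entries.

    Returns (matches, unmatched_track_rows, unmatched_detection_cols).
    Matched pairs costing more than ``max_cost`` are demoted to unmatched.
    Ties are broken deterministically: rows are scanned in order, so equal
    -cost assignments resolve by (track index, detection index).
    """
    n_rows, n_cols = C.shape
    if n_rows == 0 or n_cols == 0:
        return [], list(range(n_rows)), list(range(n_cols))
    # replace infeasible entries with a finite penalty so the solver runs;
    # any match landing on one is discarded afterwards
    feasible = np.isfinite(C)
    penalty = (C[feasible].max() if feasible.any() else 0.0) + 1e6
    C_solv = np.where(feasible, C, penalty)
    rows, cols = linear_sum_assignment(C_solv)
    matches: list[tuple[int, int]] = []
    unmatched_rows = set(range(n_rows))
    unmatched_cols = set(range(n_cols))
    for r, c in zip(rows, cols):
        if feasible[r, c] and C[r, c] <= max_cost:
            matches.append((int(r), int(c)))
            unmatched_rows.discard(r)
            unmatched_cols.discard(c)
    return matches, sorted(unmatched_rows), sorted(unmatched_cols)


# ---------------------------------------------------------------------------
# Tracker
# ---------------------------------------------------------------------------

class Tracker:
    """Frame-by-frame multi-object tracker with identity voting.

    Parameters
    ----------
    cost_config : CostConfig
        Association weights and thresholds.
    model : MotionModel
        Shared constant-velocity Kalman model (F, H, Q, R).
    n_init : int
        Consecutive hits for a TENTATIVE track to become CONFIRMED.
    max_age : int
        Frames without a match before a CONFIRMED track is DELETED.
        TENTATIVE tracks are deleted on their first miss (the
        confirmation rule requires consecutive hits).
    alpha : float
        EMA momentum for the appearance state.
    """

    def __init__(
        self,
        cost_config: CostConfig | None = None,
        model: MotionModel | None = None,
        n_init: int = 3,
        max_age: int = 30,
        alpha: float = 0.9,
    ):
        self.cfg = cost_config or CostConfig()
        self.model = model or MotionModel()
        self.n_init = n_init
        self.max_age = max_age
        self.alpha = alpha
        self.tracks: list[Track] = []
        self._next_id = 1
        self.n_spawned = 0
        self.n_confirmed = 0
        self.n_deleted = 0
        #: (track, detection index) pairs matched in the most recent step
        self.last_matches: list[tuple[Track, int]] = []

    def _spawn(self, det: Detection) -> Track:
        mean, cov = self.model.initiate(det.to_measurement())
        votes = np.zeros(len(det.class_scores))
        if votes.size:
            votes[int(np.argmax(det.class_scores))] = 1
        t = Track(
            track_id=self._next_id,
            kalman=KalmanState(mean, cov),
            appearance=det.embedding.copy(),
            alpha=self.alpha,
            identity_votes=votes,
        )
        if self.n_init <= 1:
            t.status = TrackStatus.CONFIRMED
            self.n_confirmed += 1
        self._next_id += 1
        self.n_spawned += 1
        return t

    def step(self, dets: Sequence[Detection]) -> list[Track]:
        """Advance one frame: predict, associate, update, manage lifecycle.

        Returns the list of live (non-deleted) tracks after the update.
        All detections must share one frame index.
        """
        if dets and len({d.frame for d in dets}) > 1:
            raise TrackingError("detections passed to step() must share one frame index")

        for t in self.tracks:
            predict(t, self.model)

        A_a = appearance_cost(self.tracks, dets)
        A_m = motion_cost(self.tracks, dets, self.model, self.cfg.gate_threshold)
        C = combined_cost(A_a, A_m, self.cfg)
        matches, unmatched_tracks, unmatched_dets = associate(C, self.cfg.max_cost)

        self.last_matches = [(self.tracks[ti], di) for ti, di in matches]
        for ti, di in matches:
            t, d = self.tracks[ti], dets[di]
            nsa_update(t, d, self.model)
            ema_update(t, d)
            if d.class_scores.size:
                if t.identity_votes.size != d.class_scores.size:
                    raise TrackingError("identity label count changed mid-run")
                t.identity_votes[int(np.argmax(d.class_scores))] += 1
            if t.status is TrackStatus.TENTATIVE and t.hits >= self.n_init:
                t.status = TrackStatus.CONFIRMED
                self.n_confirmed += 1

        for ti in unmatched_tracks:
            t = self.tracks[ti]
            if t.status is TrackStatus.TENTATIVE:
                t.status = TrackStatus.DELETED
            elif t.time_since_update > self.max_age:
                t.status = TrackStatus.DELETED

        for di in unmatched_dets:
            self.tracks.append(self._spawn(dets[di]))

        self.n_deleted += sum(1 for t in self.tracks if t.status is TrackStatus.DELETED)
        self.tracks = [t for t in self.tracks if t.status is not TrackStatus.DELETED]
        return self.tracks
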