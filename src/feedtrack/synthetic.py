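"""Synthetic pen scenarios with full ground truth.

Emulates a fixed overhead camera watching a feed trough: each individual
alternates rest / picking / feeding bouts, with feeding confined to
configured delivery windows (two per day on a real farm; two per run
here, scaled to the simulated duration). Bout lengths are log-normal, so
durations have realistic autocorrelation rather than per-frame coin-flip
structure. Trajectories are smooth (speed-capped pursuit of per-bout
anchor points plus a slow sinusoidal wander), and the per-frame behavior
labels are *derived from the generated geometry itself* — a frame is
labeled feeding exactly when the mouth proxy falls at/below the fitted
feed curve inside the trough — so ground truth is consistent with the
classifier's geometric definition by construction.

Corruption model: boxes are dropped independently (miss rate), jittered
with Gaussian pixel noise, and embeddings are noisy copies of per-identity
unit prototypes; designated confusable pairs get prototypes at reduced
angular separation, concentrating identity errors in those pairs the way
visually similar animals do. Occlusion is modeled as visibility gaps.

Schedule sampling rules (the contract tests rely on):

* the first bout is always REST, lasting at least ``min_initial_rest_s``;
* inside a feeding window, bout states are drawn i.i.d. with
  probabilities ``p_feed, p_pick_in, p_rest_in`` = (0.6, 0.25, 0.15);
  outside, (pick, rest) with (0.2, 0.8);
* FEEDING bouts start only inside a window and are clamped to end at
  least ``exit_margin_s`` before the window closes (if less than 1 s of
  room remains, a picking bout is drawn instead), so the mouth is back
  above the curve before the window ends;
* bout lengths are log-normal with arithmetic means (30, 8, 15) s for
  feed/pick/rest and log-sd 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .behavior import Behavior
from .geometry import BoundaryCurve, FeedPoint, TroughRegion, fit_boundary

BEHAVIOR_CODES = {None: 0, Behavior.FEEDING: 1, Behavior.PICKING: 2}
CODE_TO_BEHAVIOR = {0: None, 1: Behavior.FEEDING, 2: Behavior.PICKING}

# bout states
REST, PICK, FEED = "rest", "pick", "feed"

#: arithmetic-mean bout lengths (s) and shared log-sd of the log-normals
BOUT_MEAN_S = {FEED: 30.0, PICK: 8.0, REST: 15.0}
BOUT_LOG_SD = 0.6
#: bout-state probabilities inside / outside feeding windows
P_IN_WINDOW = {FEED: 0.6, PICK: 0.25, REST: 0.15}
P_OUT_WINDOW = {PICK: 0.2, REST: 0.8}

# trajectory constants (pixels; 1920x1080 frame)
IMAGE_W, IMAGE_H = 1920, 1080
TROUGH_POLY = ((100.0, 650.0), (1820.0, 650.0), (1820.0, 1000.0), (100.0, 1000.0))
SLOT_X_RANGE = (180.0, 1740.0)
SLOT_MIN_SEP = 150.0
REST_Y = 400.0          # mouth height at rest, well above the rail
PICK_HEIGHT = 40.0      # mouth this far above the feed curve while picking
FEED_DEPTH = 30.0       # mouth this far below the feed curve while feeding
MAX_SPEED = 15.0        # px / frame cap on mouth speed
MAX_ACCEL = 1.0         # px / frame^2 cap — animals change speed smoothly
WANDER_AMP = 25.0       # px, slow sideways sway
MIN_INITIAL_REST_S = 2.0
EXIT_MARGIN_S = 1.0


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator knobs; defaults are the standard noisy test conditions."""

    n_individuals: int = 6
    duration_s: float = 300.0
    fps: float = 25.0
    embedding_dim: int = 64
    feeding_windows: tuple[tuple[float, float], ...] | None = None
    miss_rate: float = 0.05
    jitter_px: float = 2.0
    embed_noise: float = 0.05
    # With noisy embeddings, a pair at prototype cosine s is misread at
    # rate ~ Phi(-sqrt((1-s)/2)/embed_noise) per detection; s = 0.98 with
    # noise 0.05 puts pair confusion at ~2%, the rate seen between
    # visually similar herd-mates.
    confusable_pairs: tuple[tuple[int, int], ...] = ((0, 2),)
    confusable_sim: float = 0.98
    occlusion_rate: float = 0.02     # gap starts per visible second
    occlusion_mean_s: float = 2.0
    score_temperature: float = 0.05  # softmax sharpness of identity scores
    curve_degree: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ScenarioError("duration_s must be positive")
        for p, name in [
            (self.miss_rate, "miss_rate"),
            (self.embed_noise, "embed_noise"),
            (self.occlusion_rate, "occlusion_rate"),
        ]:
            if p < 0 or (name == "miss_rate" and p > 1):
                raise ScenarioError(f"{name} out of range: {p}")
        max_slots = int((SLOT_X_RANGE[1] - SLOT_X_RANGE[0]) / SLOT_MIN_SEP) + 1
        if self.n_individuals > max_slots:
            raise ScenarioError(
                f"{self.n_individuals} individuals exceed the {max_slots} trough slots"
            )
        if self.n_individuals < 1:
            raise ScenarioError("need at least one individual")
        for a, b in self.confusable_pairs:
            if not (0 <= a < self.n_individuals and 0 <= b < self.n_individuals) or a == b:
                raise ScenarioError(f"invalid confusable pair ({a}, {b})")
        for s, e in self.windows:
            if not (0 <= s < e <= self.duration_s):
                raise ScenarioError(f"feeding window ({s}, {e}) outside [0, duration]")

    @property
    def windows(self) -> tuple[tuple[float, float], ...]:
        """Feeding windows; default two bouts emulating morning/evening delivery."""
        if self.feeding_windows is not None:
            return self.feeding_windows
        d = self.duration_s
        return ((0.05 * d, 0.35 * d), (0.55 * d, 0.90 * d))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @classmethod
    def noise_free(cls, **overrides) -> "ScenarioConfig":
        """Uncorrupted conditions: exact boxes, exact embeddings, no gaps."""
        base = dict(
            duration_s=600.0,
            miss_rate=0.0,
            jitter_px=0.0,
            embed_noise=0.0,
            confusable_pairs=(),
            occlusion_rate=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def default_noisy(cls, **overrides) -> "ScenarioConfig":
        return cls(**overrides)

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Everything the evaluator needs: boxes, labels, geometry, schedules."""

    cfg: ScenarioConfig
    boxes: np.ndarray        # (n_frames, n_ids, 4) — x, y, w, h
    behavior: np.ndarray     # (n_frames, n_ids) codes per BEHAVIOR_CODES
    visible: np.ndarray      # (n_frames, n_ids) bool
    region: TroughRegion
    feed_points: list[FeedPoint]
    curve: BoundaryCurve
    prototypes: np.ndarray   # (n_ids, D) unit identity prototypes
    schedules: list[list[tuple[str, float, float]]]  # per id: (state, t0, t1)
    slot_x: np.ndarray

    def duration_summaries(self, stride: int = 3):
        """True per-(identity, behavior) counts at the detector's sampled frames."""
        from .behavior import DurationSummary

        frames = np.arange(0, self.boxes.shape[0], stride)
        out = []
        for i in range(self.cfg.n_individuals):
            codes = self.behavior[frames, i]
            for beh in (Behavior.FEEDING, Behavior.PICKING):
                d = int(np.sum(codes == BEHAVIOR_CODES[beh]))
                out.append(
                    DurationSummary(
                        identity=i,
                        behavior=beh,
                        d=d,
                        minutes=d * stride / (self.cfg.fps * 60.0),
                        fps=self.cfg.fps,
                        stride=stride,
                    )
                )
        return out


@dataclass(frozen=True)
class RenderedDetection:
    """A corrupted detection plus its ground-truth provenance."""

    frame: int
    box: tuple[float, float, float, float]
    confidence: float
    class_scores: np.ndarray
    embedding: np.ndarray
    true_identity: int
    true_behavior: Behavior | None


# ---------------------------------------------------------------------------
# geometry + schedule + trajectory synthesis
# ---------------------------------------------------------------------------

def make_geometry(cfg: ScenarioConfig) -> tuple[TroughRegion, list[FeedPoint], BoundaryCurve]:
    """Trough polygon and 13 marked feed-surface points on a gentle parabola."""
    region = TroughRegion(TROUGH_POLY)
    xs = np.linspace(TROUGH_POLY[0][0], TROUGH_POLY[1][0], 13)
    ys = 800.0 + 40.0 * ((xs - 960.0) / 860.0) ** 2
    pts = [FeedPoint(float(x), float(y)) for x, y in zip(xs, ys)]
    curve = fit_boundary(pts, degree=cfg.curve_degree)
    return region, pts, curve


def _bout_duration(rng: np.random.Generator, state: str) -> float:
    mean = BOUT_MEAN_S[state]
    mu = np.log(mean) - BOUT_LOG_SD**2 / 2.0
    return float(rng.lognormal(mu, BOUT_LOG_SD))


def _window_at(t: float, windows) -> tuple[float, float] | None:
    for w in windows:
        if w[0] <= t < w[1]:
            return w
    return None


def sample_schedule(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> list[tuple[str, float, float]]:
    """Semi-Markov bout schedule for one individual (see module docstring)."""
    D = cfg.duration_s
    segs: list[tuple[str, float, float]] = []
    t = 0.0
    first = True
    while t < D:
        w = _window_at(t, cfg.windows)
        if first:
            state = REST
            dur = max(_bout_duration(rng, REST), MIN_INITIAL_REST_S)
            first = False
        elif w is not None:
            states = list(P_IN_WINDOW)
            state = states[rng.choice(len(states), p=[P_IN_WINDOW[s] for s in states])]
            if state == FEED and w[1] - EXIT_MARGIN_S - t < 1.0:
                state = PICK
            dur = _bout_duration(rng, state)
        else:
            states = list(P_OUT_WINDOW)
            state = states[rng.choice(len(states), p=[P_OUT_WINDOW[s] for s in states])]
            dur = _bout_duration(rng, state)
        t1 = min(t + dur, D)
        if state == FEED:
            t1 = min(t1, w[1] - EXIT_MARGIN_S)
        if t1 > t:
            segs.append((state, t, t1))
            t = t1
        else:  # zero-length after clamping; nudge forward
            t += 0.04
    return segs


def _state_at(segs, t: float) -> str:
    for state, t0, t1 in segs:
        if t0 <= t < t1:
            return state
    return segs[-1][0] if segs else REST


def generate_scenario(cfg: ScenarioConfig) -> GroundTruth:
    """Generate ground truth: schedules, trajectories, boxes, labels, geometry.

    Deterministic for a fixed ``cfg.seed``. Behavior labels are computed by
    classifying each frame's mouth proxy against the generated geometry, so
    they are exactly the labels an ideal detector-classifier would produce.
    """
    rng = np.random.default_rng(cfg.seed)
    region, pts, curve = make_geometry(cfg)
    n, nf = cfg.n_individuals, cfg.n_frames

    slot_x = np.linspace(*SLOT_X_RANGE, n) if n > 1 else np.array(
        [(SLOT_X_RANGE[0] + SLOT_X_RANGE[1]) / 2]
    )
    widths = 110.0 + 4.0 * (np.arange(n) % 5)
    heights = 125.0 + 3.0 * (np.arange(n) % 4)
    wander_period = 30.0 + 7.0 * np.arange(n)
    wander_phase = rng.uniform(0, 2 * np.pi, size=n)

    schedules = [sample_schedule(cfg, rng) for _ in range(n)]

    boxes = np.zeros((nf, n, 4))
    behavior = np.zeros((nf, n), dtype=np.int8)
    visible = np.ones((nf, n), dtype=bool)
    c = curve.coefficients

    for i in range(n):
        mx, my = float(slot_x[i]), REST_Y
        vx = vy = 0.0
        segs = schedules[i]
        seg_idx = 0
        for f in range(nf):
            t = f / cfg.fps
            while seg_idx < len(segs) - 1 and t >= segs[seg_idx][2]:
                seg_idx += 1
            state = segs[seg_idx][0]
            wander = WANDER_AMP * np.sin(
                2 * np.pi * t / wander_period[i] + wander_phase[i]
            )
            if state == REST:
                tx, ty = slot_x[i] + wander, REST_Y
            else:
                tx = slot_x[i] + 0.3 * wander
                y_curve = float(np.polyval(c, tx))
                ty = y_curve - PICK_HEIGHT if state == PICK else y_curve + FEED_DEPTH
            # accel-capped pursuit: approach at a speed that can still brake
            # to a stop at the target, so the mouth settles without ringing
            dx, dy = tx - mx, ty - my
            dist = float(np.hypot(dx, dy))
            v_des = min(MAX_SPEED, np.sqrt(2.0 * MAX_ACCEL * dist))
            if dist > 1e-9:
                dvx, dvy = v_des * dx / dist - vx, v_des * dy / dist - vy
            else:
                dvx, dvy = -vx, -vy
            dv = float(np.hypot(dvx, dvy))
            if dv > MAX_ACCEL:
                scale = MAX_ACCEL / dv
                dvx, dvy = dvx * scale, dvy * scale
            vx, vy = vx + dvx, vy + dvy
            mx, my = mx + vx, my + vy

            w, h = widths[i], heights[i]
            boxes[f, i] = (mx - w / 2.0, my - h, w, h)
            if region.contains(mx, my):
                behavior[f, i] = (
                    BEHAVIOR_CODES[Behavior.FEEDING]
                    if my >= float(np.polyval(c, mx))
                    else BEHAVIOR_CODES[Behavior.PICKING]
                )

    # occlusion gaps: Poisson starts at occlusion_rate per visible second
    if cfg.occlusion_rate > 0:
        p_start = cfg.occlusion_rate / cfg.fps
        for i in range(n):
            f = 0
            while f < nf:
                if rng.uniform() < p_start:
                    gap = max(
                        1,
                        int(
                            rng.lognormal(
                                np.log(cfg.occlusion_mean_s) - 0.125, 0.5
                            )
                            * cfg.fps
                        ),
                    )
                    visible[f : f + gap, i] = False
                    f += gap
                else:
                    f += 1

    prototypes = make_prototypes(cfg, np.random.default_rng([cfg.seed, 7]))
    return GroundTruth(
        cfg=cfg,
        boxes=boxes,
        behavior=behavior,
        visible=visible,
        region=region,
        feed_points=pts,
        curve=curve,
        prototypes=prototypes,
        schedules=schedules,
        slot_x=slot_x,
    )


def make_prototypes(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit identity prototypes; confusable pairs at cosine ``confusable_sim``.

    Random directions in dimension >= 32 are near-orthogonal, so
    non-confusable identities sit at cosine distance ~1 from each other.
    """
    protos = rng.normal(size=(cfg.n_individuals, cfg.embedding_dim))
    protos /= np.linalg.norm(protos, axis=1, keepdims=True)
    for a, b in cfg.confusable_pairs:
        u = protos[a]
        v = protos[b] - (protos[b] @ u) * u
        v /= np.linalg.norm(v)
        protos[b] = cfg.confusable_sim * u + np.sqrt(1 - cfg.confusable_sim**2) * v
    return protos


def render_detections(
    gt: GroundTruth,
    cfg: ScenarioConfig | None = None,
    frames: Sequence[int] | None = None,
) -> list[RenderedDetection]:
    """Corrupt ground truth into a detection stream.

    Each visible true box is emitted with probability ``1 - miss_rate``;
    boxes get N(0, jitter_px^2) noise on all four coordinates, embeddings
    are re-normalized noisy prototypes, identity scores are a sharpened
    softmax of prototype similarities, and confidences are uniform on
    [0.5, 1] (at or above the working confidence threshold).
    """
    cfg = cfg or gt.cfg
    rng = np.random.default_rng([cfg.seed, 1])
    if frames is None:
        frames = range(gt.boxes.shape[0])
    n = cfg.n_individuals
    out: list[RenderedDetection] = []
    for f in frames:
        for i in range(n):
            if not gt.visible[f, i]:
                continue
            if cfg.miss_rate > 0 and rng.uniform() < cfg.miss_rate:
                continue
            box = gt.boxes[f, i] + rng.normal(0, cfg.jitter_px, size=4) if cfg.jitter_px > 0 else gt.boxes[f, i].copy()
            box[2] = max(box[2], 5.0)
            box[3] = max(box[3], 5.0)
            emb = gt.prototypes[i].copy()
            if cfg.embed_noise > 0:
                emb = emb + rng.normal(0, cfg.embed_noise, size=emb.shape)
            emb /= np.linalg.norm(emb)
            sims = gt.prototypes @ emb
            logits = sims / cfg.score_temperature
            logits -= logits.max()
            scores = np.exp(logits)
            scores /= scores.sum()
            out.append(
                RenderedDetection(
                    frame=int(f),
                    box=tuple(float(v) for v in box),
                    confidence=float(rng.uniform(0.5, 1.0)),
                    class_scores=scores,
                    embedding=emb,
                    true_identity=i,
                    true_behavior=CODE_TO_BEHAVIOR[int(gt.behavior[f, i])],
                )
            )
    return out


def schedule_state_seconds(segs: Sequence[tuple[str, float, float]]) -> dict[str, float]:
    """Total seconds per bout state in one schedule."""
    totals = {REST: 0.0, PICK: 0.0, FEED: 0.0}
    for state, t0, t1 in segs:
        totals[state] += t1 - t0
    return totals
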