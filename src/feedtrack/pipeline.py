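"""End-to-end driver: detections -> tracks -> zones -> ethogram -> reports.

The flow mirrors the monitoring setup it models: frames are sampled at a
fixed stride, the tracker associates each sampled frame's detections to
individual tracks, each matched box's mouth proxy is classified against
the pen geometry, and the resulting event stream is reduced to
per-individual durations and a 12-s dot raster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .behavior import (
    Behavior,
    BehaviorEvent,
    DotRaster,
    DurationSummary,
    accumulate_durations,
    build_raster,
    classify_behavior,
    mouth_proxy,
    sample_frames,
)
from .geometry import BoundaryCurve, TroughRegion, fit_boundary
from .tracking import CostConfig, Detection, Tracker, TrackStatus

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name and frame index."""


@dataclass(frozen=True)
class MatchRecord:
    """One confirmed track-detection match at one sampled frame."""

    frame: int
    det_index: int          # index within that frame's detection list
    track_id: int
    identity: int
    behavior: Behavior | None
    box: tuple[float, float, float, float]


@dataclass
class PipelineResult:
    events: list[BehaviorEvent]
    durations: list[DurationSummary]
    rasters: list[DotRaster]
    matches: list[MatchRecord]
    counts: dict[str, int] = field(default_factory=dict)


def group_by_frame(dets: Sequence[Detection]) -> dict[int, list[Detection]]:
    by_frame: dict[int, list[Detection]] = {}
    for d in dets:
        by_frame.setdefault(d.frame, []).append(d)
    return by_frame


def run_tracking(
    frames: Sequence[int],
    dets_by_frame: Mapping[int, Sequence[Detection]],
    tracker: Tracker,
    curve: BoundaryCurve,
    region: TroughRegion,
    proxy_mode: str = "bottom_center",
    include_tentative: bool = False,
) -> tuple[list[BehaviorEvent], list[MatchRecord]]:
    """Track through the sampled frames and classify matched boxes.

    Behavior events come from CONFIRMED tracks by default: tentative
    tracks are one-or-two-frame hypotheses whose identity vote is still
    unstable, and counting them inflates durations with spurious
    detections.
    """
    events: list[BehaviorEvent] = []
    matches: list[MatchRecord] = []
    for f in frames:
        dets = list(dets_by_frame.get(f, []))
        try:
            tracker.step(dets)
        except Exception as exc:
            raise PipelineError(f"tracking failed at frame {f}: {exc}") from exc
        for track, di in tracker.last_matches:
            if not include_tentative and track.status is not TrackStatus.CONFIRMED:
                continue
            det = dets[di]
            behavior = classify_behavior(det.box, curve, region, proxy_mode)
            matches.append(
                MatchRecord(
                    frame=f,
                    det_index=di,
                    track_id=track.track_id,
                    identity=track.identity,
                    behavior=behavior,
                    box=det.box,
                )
            )
            if behavior is not None:
                events.append(
                    BehaviorEvent(
                        frame=f,
                        track_id=track.track_id,
                        identity=track.identity,
                        behavior=behavior,
                        position=mouth_proxy(det.box, proxy_mode),
                    )
                )
    return events, matches


def run_pipeline(cfg) -> PipelineResult:
    """Execute the full file-based pipeline from a :class:`~feedtrack.io.RunConfig`.

    Reads geometry and detections, fits the boundary curve, tracks,
    classifies, and writes events/durations/raster outputs to
    ``cfg.output_dir``. Reproducible: the only stochastic stage is the
    scenario generator, which is upstream of this entry point.
    """
    from . import io as ftio

    for name in ("geometry", "detections", "embeddings"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise ftio.InputError(f"{name} file missing: {p}")

    region, feed_points, degree = ftio.read_geometry(cfg.geometry)
    curve = fit_boundary(feed_points, degree=degree)
    logger.info(
        "geometry: %d feed points, degree-%d curve, rss=%.3g",
        len(feed_points), degree, curve.rss,
    )

    dets = ftio.read_detections(cfg.detections, cfg.embeddings, cfg.confidence_min)
    by_frame = group_by_frame(dets)
    total_frames = (max(by_frame) + 1) if by_frame else 0
    frames = sample_frames(total_frames, cfg.stride)
    logger.info(
        "detections: %d rows after confidence >= %.2f filter, %d sampled frames",
        len(dets), cfg.confidence_min, len(frames),
    )

    tracker = Tracker(
        cost_config=CostConfig(
            lambda_weight=cfg.lambda_weight,
            gate_threshold=cfg.gate_threshold,
            max_cost=cfg.max_cost,
        ),
        n_init=cfg.n_init,
        max_age=cfg.max_age,
        alpha=cfg.alpha,
    )
    events, match_records = run_tracking(
        frames, by_frame, tracker, curve, region,
        proxy_mode=cfg.proxy_mode, include_tentative=cfg.include_tentative,
    )
    durations = accumulate_durations(events, fps=cfg.fps, stride=cfg.stride)
    rasters = build_raster(events, window_s=cfg.window_s, fps=cfg.fps)

    counts = {
        "detections_read": len(dets),
        "sampled_frames": len(frames),
        "tracks_spawned": tracker.n_spawned,
        "tracks_confirmed": tracker.n_confirmed,
        "events": len(events),
    }
    logger.info("pipeline counts: %s", counts)

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ftio.write_events(out / "events.csv", events, fps=cfg.fps)
    ftio.write_durations(out / "durations.csv", durations)
    return PipelineResult(
        events=events,
        durations=durations,
        rasters=rasters,
        matches=match_records,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# in-memory synthetic experiments
# ---------------------------------------------------------------------------

def run_synthetic(
    scenario_cfg,
    stride: int = 3,
    confidence_min: float = 0.5,
    include_tentative: bool = False,
    **tracker_kwargs,
):
    """Generate a scenario, track it, and return everything for evaluation.

    Detections are rendered only at the sampled frames (the detector in
    the modeled system runs every ``stride`` frames). Returns
    ``(gt, rendered_by_frame, result)`` where ``rendered_by_frame`` keeps
    the ground-truth provenance of every detection the tracker saw.
    """
    from .synthetic import generate_scenario, render_detections

    gt = generate_scenario(scenario_cfg)
    frames = sample_frames(gt.boxes.shape[0], stride)
    rendered = render_detections(gt, frames=frames)
    rendered_by_frame: dict[int, list] = {}
    dets_by_frame: dict[int, list[Detection]] = {}
    for r in rendered:
        if r.confidence < confidence_min:
            continue
        rendered_by_frame.setdefault(r.frame, []).append(r)
        dets_by_frame.setdefault(r.frame, []).append(
            Detection(
                frame=r.frame,
                box=r.box,
                confidence=r.confidence,
                class_scores=r.class_scores,
                embedding=r.embedding,
            )
        )
    tracker = Tracker(**tracker_kwargs)
    events, matches = run_tracking(
        frames, dets_by_frame, tracker, gt.curve, gt.region,
        include_tentative=include_tentative,
    )
    durations = accumulate_durations(events, fps=scenario_cfg.fps, stride=stride)
    rasters = build_raster(events, fps=scenario_cfg.fps)
    result = PipelineResult(
        events=events,
        durations=durations,
        rasters=rasters,
        matches=matches,
        counts={
            "detections": sum(len(v) for v in dets_by_frame.values()),
            "sampled_frames": len(frames),
            "tracks_spawned": tracker.n_spawned,
            "events": len(events),
        },
    )
    return gt, rendered_by_frame, result


def evaluate_against_truth(gt, rendered_by_frame, result, stride: int = 3) -> dict:
    """Score a synthetic run against its own ground truth.

    Returns behavior-classification accuracy over matched in-trough
    detections, identity accuracy and the K-class identity confusion
    matrix, per-(identity, behavior) duration MAE in minutes, and
    mAP at IoU 0.5 / 0.50:0.95 of the identity-labeled matched boxes.
    """
    from . import evaluation as ev
    from . import io as ftio
    import numpy as np

    n = gt.cfg.n_individuals

    true_ids, pred_ids = [], []
    beh_total = beh_correct = 0
    predictions = []
    for m in result.matches:
        r = rendered_by_frame[m.frame][m.det_index]
        true_ids.append(r.true_identity)
        pred_ids.append(m.identity)
        if r.true_behavior is not None:
            beh_total += 1
            if m.behavior == r.true_behavior:
                beh_correct += 1
        predictions.append(
            ev.BoxPrediction(frame=m.frame, label=m.identity, box=m.box,
                             confidence=rendered_by_frame[m.frame][m.det_index].confidence)
        )

    frames = range(0, gt.boxes.shape[0], stride)
    truth_boxes = [
        ev.BoxTruth(frame=f, label=i, box=tuple(gt.boxes[f, i]))
        for f in frames
        for i in range(n)
        if gt.visible[f, i]
    ]
    map50, map50_95 = ev.map_range(predictions, truth_boxes)

    confusion = ev.identity_confusion(true_ids, pred_ids, n) if true_ids else np.zeros((n, n), int)
    # per-detection confusion (argmax identity score vs truth): the
    # detector-classifier's view, before track-level vote pooling
    det_true, det_pred = [], []
    for dets in rendered_by_frame.values():
        for r in dets:
            det_true.append(r.true_identity)
            det_pred.append(int(np.argmax(r.class_scores)))
    det_confusion = ev.identity_confusion(det_true, det_pred, n)
    est = ftio.complete_durations(result.durations, list(range(n)), gt.cfg.fps, stride)
    mae = ev.duration_mae(est, gt.duration_summaries(stride))

    id_total = len(true_ids)
    return {
        "behavior_accuracy": beh_correct / beh_total if beh_total else None,
        "n_behavior_events": beh_total,
        "identity_accuracy": float(np.trace(confusion)) / id_total if id_total else None,
        "identity_confusion": confusion,
        "detection_confusion": det_confusion,
        "duration_mae_min": mae,
        "map50": map50,
        "map50_95": map50_95,
    }
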