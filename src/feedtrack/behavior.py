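"""Ethogram construction: feeding/picking events, durations, dot rasters.

A tracked detection becomes a behavior event by classifying a mouth
proxy — by default the bottom-center of the face box — against the pen
geometry: inside the trough and at/below the feed-surface curve is
FEEDING, inside but above the curve is PICKING, outside the trough is no
event. Detection runs every ``stride`` frames (default 3) of
``fps``-rate video (default 25), so a behavior observed ``d`` times has
duration

    t_b = d * stride / (fps * 60)   minutes,

which with the defaults is d * 3 / 1500. Distributions are summarized as
a dot raster: one dot per 12-second window in which the behavior occurred.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .geometry import BoundaryCurve, TroughRegion, Zone, classify_zone


class Behavior(Enum):
    FEEDING = "feeding"
    PICKING = "picking"


@dataclass(frozen=True)
class BehaviorEvent:
    """One in-trough observation of one individual at one sampled frame."""

    frame: int
    track_id: int
    identity: int
    behavior: Behavior
    position: tuple[float, float]


@dataclass(frozen=True)
class DurationSummary:
    """Per (identity, behavior) event count and derived duration."""

    identity: int
    behavior: Behavior
    d: int
    minutes: float
    fps: float = 25.0
    stride: int = 3


@dataclass(frozen=True)
class DotRaster:
    """Sparse per-identity raster: one dot per window with activity.

    ``dots`` holds (window_start_s, behavior, position) triples ordered in
    time; consecutive dots of one behavior are at least one window apart.
    """

    identity: int
    dots: tuple[tuple[float, Behavior, tuple[float, float]], ...]


ZONE_TO_BEHAVIOR = {
    Zone.FEEDING_ZONE: Behavior.FEEDING,
    Zone.PICKING_ZONE: Behavior.PICKING,
    Zone.OUTSIDE: None,
}


def mouth_proxy(
    box: tuple[float, float, float, float], mode: str = "bottom_center"
) -> tuple[float, float]:
    """Image point standing in for the mouth. Modes: bottom_center, center."""
    x, y, w, h = box
    if mode == "bottom_center":
        return (x + w / 2.0, y + h)
    if mode == "center":
        return (x + w / 2.0, y + h / 2.0)
    raise ValueError(f"unknown mouth proxy mode: {mode!r}")


def classify_behavior(
    box: tuple[float, float, float, float],
    curve: BoundaryCurve,
    region: TroughRegion,
    proxy_mode: str = "bottom_center",
) -> Behavior | None:
    """Map a face box to FEEDING / PICKING / None via the zone partition."""
    zone = classify_zone(mouth_proxy(box, proxy_mode), curve, region)
    return ZONE_TO_BEHAVIOR[zone]


def accumulate_durations(
    events: list[BehaviorEvent], fps: float = 25.0, stride: int = 3
) -> list[DurationSummary]:
    """Event counts and durations per (identity, behavior), sorted by key."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    counts: dict[tuple[int, Behavior], int] = {}
    for ev in events:
        counts[(ev.identity, ev.behavior)] = counts.get((ev.identity, ev.behavior), 0) + 1
    return [
        DurationSummary(
            identity=ident,
            behavior=beh,
            d=d,
            minutes=d * stride / (fps * 60.0),
            fps=fps,
            stride=stride,
        )
        for (ident, beh), d in sorted(counts.items(), key=lambda kv: (kv[0][0], kv[0][1].value))
    ]


def build_raster(
    events: list[BehaviorEvent], window_s: float = 12.0, fps: float = 25.0
) -> list[DotRaster]:
    """Collapse events to one dot per (identity, behavior, 12-s window).

    The dot is placed at the first event of the window. Identities are
    returned in ascending order.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    first_in_window: dict[tuple[int, Behavior, int], BehaviorEvent] = {}
    for ev in sorted(events, key=lambda e: e.frame):
        widx = int((ev.frame / fps) // window_s)
        first_in_window.setdefault((ev.identity, ev.behavior, widx), ev)
    per_identity: dict[int, list[tuple[float, Behavior, tuple[float, float]]]] = {}
    for (ident, beh, widx), ev in sorted(
        first_in_window.items(), key=lambda kv: (kv[0][0], kv[0][2], kv[0][1].value)
    ):
        per_identity.setdefault(ident, []).append((widx * window_s, beh, ev.position))
    return [DotRaster(identity=i, dots=tuple(d)) for i, d in sorted(per_identity.items())]


def sample_frames(total_frames: int, stride: int = 3) -> list[int]:
    """Frame indices processed by the detector: 0, stride, 2*stride, ..."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return list(range(0, total_frames, stride))
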