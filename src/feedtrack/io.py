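"""File formats and run configuration.

All on-disk formats are plain delimited text:

* **detections** — MOTChallenge-style rows
  ``frame,-1,x,y,w,h,confidence,score_1,...,score_K`` with a sidecar
  embedding matrix (row i belongs to detection row i) whose first line
  declares the dimension (``# dim D``);
* **geometry** — YAML with ``trough_polygon``, ``feed_points`` and
  ``curve_degree``;
* **events / durations / tracks / ground truth** — headered CSV.

Every writer's output re-parses under the matching reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import Behavior, BehaviorEvent, DurationSummary
from .geometry import FeedPoint, GeometryError, TroughRegion
from .synthetic import GroundTruth, RenderedDetection
from .tracking import Detection


class InputError(ValueError):
    """Malformed or inconsistent input files."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Tracker defaults follow the method's stated settings (EMA momentum
    0.9, appearance weight 0.98, confidence floor 0.5); timing defaults
    are 25 fps video sampled every 3 frames with 12-s raster windows.
    """

    detections: Path | None = None
    embeddings: Path | None = None
    geometry: Path | None = None
    output_dir: Path = Path("feedtrack_out")
    # tracker
    alpha: float = 0.9
    lambda_weight: float = 0.98
    gate_threshold: float = 9.4877
    n_init: int = 3
    max_age: int = 30
    max_cost: float = 0.7
    # behavior
    fps: float = 25.0
    stride: int = 3
    window_s: float = 12.0
    proxy_mode: str = "bottom_center"
    include_tentative: bool = False
    # filters
    confidence_min: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):  # nested sections are flattened
                flat.update(val)
            else:
                flat[key] = val
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for p in ("detections", "embeddings", "geometry", "output_dir"):
            if p in flat and flat[p] is not None:
                flat[p] = Path(flat[p])
        return cls(**flat)


# ---------------------------------------------------------------------------
# detections + embeddings
# ---------------------------------------------------------------------------

def write_detections(
    path: str | Path,
    emb_path: str | Path,
    detections: list[RenderedDetection] | list[Detection],
) -> None:
    path, emb_path = Path(path), Path(emb_path)
    dim = len(detections[0].embedding) if detections else 0
    with open(path, "w") as fh:
        for d in detections:
            x, y, w, h = d.box
            scores = ",".join(f"{s:.8f}" for s in d.class_scores)
            fh.write(f"{d.frame},-1,{x:.4f},{y:.4f},{w:.4f},{h:.4f},{d.confidence:.6f},{scores}\n")
    with open(emb_path, "w") as fh:
        fh.write(f"# dim {dim}\n")
        for d in detections:
            fh.write(" ".join(f"{v:.8f}" for v in d.embedding) + "\n")


def read_detections(
    path: str | Path,
    emb_path: str | Path,
    confidence_min: float = 0.5,
) -> list[Detection]:
    """Parse detection rows, attach embeddings by row index, filter by confidence.

    Embeddings are re-normalized to unit length on load (text round-trip
    rounds the norm off). Malformed rows and row-count mismatches raise
    with the offending line number.
    """
    path, emb_path = Path(path), Path(emb_path)
    rows: list[tuple] = []
    n_scores: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            try:
                frame = int(parts[0])
                x, y, w, h = (float(v) for v in parts[2:6])
                conf = float(parts[6])
                scores = np.array([float(v) for v in parts[7:]])
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}:{lineno}: malformed detection row ({exc})")
            if n_scores is None:
                n_scores = len(scores)
            elif len(scores) != n_scores:
                raise InputError(
                    f"{path}:{lineno}: expected {n_scores} identity scores, got {len(scores)}"
                )
            rows.append((frame, (x, y, w, h), conf, scores))

    with open(emb_path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# dim"):
            raise InputError(f"{emb_path}:1: missing '# dim D' header")
        dim = int(header.split()[-1])
        emb = np.loadtxt(fh, ndmin=2) if rows else np.zeros((0, dim))
    if emb.shape[0] != len(rows):
        raise InputError(
            f"embedding rows ({emb.shape[0]}) do not match detection rows ({len(rows)})"
        )
    if len(rows) and emb.shape[1] != dim:
        raise InputError(f"embedding dimension {emb.shape[1]} != declared {dim}")

    out: list[Detection] = []
    for (frame, box, conf, scores), e in zip(rows, emb):
        if conf < confidence_min:
            continue
        norm = np.linalg.norm(e)
        if norm == 0:
            raise InputError("zero-norm embedding row")
        out.append(
            Detection(
                frame=frame, box=box, confidence=conf,
                class_scores=scores, embedding=e / norm,
            )
        )
    return out


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def write_geometry(
    path: str | Path,
    region: TroughRegion,
    feed_points: list[FeedPoint],
    curve_degree: int = 3,
) -> None:
    doc = {
        "trough_polygon": [[float(x), float(y)] for x, y in region.vertices],
        "feed_points": [[p.x, p.y] for p in feed_points],
        "curve_degree": int(curve_degree),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def read_geometry(path: str | Path) -> tuple[TroughRegion, list[FeedPoint], int]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        region = TroughRegion([tuple(v) for v in doc["trough_polygon"]])
        pts = [FeedPoint(float(x), float(y)) for x, y in doc["feed_points"]]
        degree = int(doc.get("curve_degree", 3))
    except (KeyError, TypeError, GeometryError) as exc:
        raise InputError(f"{path}: invalid geometry file ({exc})")
    return region, pts, degree


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def write_events(path: str | Path, events: list[BehaviorEvent], fps: float) -> None:
    pd.DataFrame(
        [
            {
                "frame": e.frame,
                "time_s": e.frame / fps,
                "track_id": e.track_id,
                "identity": e.identity,
                "behavior": e.behavior.value,
                "x": e.position[0],
                "y": e.position[1],
            }
            for e in events
        ],
        columns=["frame", "time_s", "track_id", "identity", "behavior", "x", "y"],
    ).to_csv(path, index=False)


def read_events(path: str | Path) -> list[BehaviorEvent]:
    df = pd.read_csv(path)
    return [
        BehaviorEvent(
            frame=int(r.frame),
            track_id=int(r.track_id),
            identity=int(r.identity),
            behavior=Behavior(r.behavior),
            position=(float(r.x), float(r.y)),
        )
        for r in df.itertuples()
    ]


def write_durations(path: str | Path, summaries: list[DurationSummary]) -> None:
    pd.DataFrame(
        [
            {
                "identity": s.identity,
                "behavior": s.behavior.value,
                "d": s.d,
                "minutes": s.minutes,
            }
            for s in summaries
        ],
        columns=["identity", "behavior", "d", "minutes"],
    ).to_csv(path, index=False)


def read_durations(
    path: str | Path, fps: float = 25.0, stride: int = 3
) -> list[DurationSummary]:
    df = pd.read_csv(path)
    return [
        DurationSummary(
            identity=int(r.identity),
            behavior=Behavior(r.behavior),
            d=int(r.d),
            minutes=float(r.minutes),
            fps=fps,
            stride=stride,
        )
        for r in df.itertuples()
    ]


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    from .synthetic import CODE_TO_BEHAVIOR

    nf, n = gt.behavior.shape
    recs = []
    for f in range(nf):
        for i in range(n):
            beh = CODE_TO_BEHAVIOR[int(gt.behavior[f, i])]
            recs.append(
                {
                    "frame": f,
                    "identity": i,
                    "x": gt.boxes[f, i, 0],
                    "y": gt.boxes[f, i, 1],
                    "w": gt.boxes[f, i, 2],
                    "h": gt.boxes[f, i, 3],
                    "behavior": beh.value if beh else "none",
                    "visible": int(gt.visible[f, i]),
                }
            )
    pd.DataFrame(recs).to_csv(path, index=False)


def complete_durations(
    summaries: list[DurationSummary],
    identities: list[int],
    fps: float = 25.0,
    stride: int = 3,
) -> list[DurationSummary]:
    """Fill missing (identity, behavior) keys with zero-count summaries.

    Duration comparison requires both tables to cover the same keys; an
    individual never observed feeding has a true zero, not a missing row.
    """
    have = {(s.identity, s.behavior) for s in summaries}
    out = list(summaries)
    for i in identities:
        for beh in (Behavior.FEEDING, Behavior.PICKING):
            if (i, beh) not in have:
                out.append(
                    DurationSummary(
                        identity=i, behavior=beh, d=0, minutes=0.0, fps=fps, stride=stride
                    )
                )
    return sorted(out, key=lambda s: (s.identity, s.behavior.value))
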