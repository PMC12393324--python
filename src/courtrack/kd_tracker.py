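"""Frame-by-frame identity tracking with a keypoint-distance association cost.

Association cost between a detection and a tracklet is the keypoint distance
(KD): the mean Euclidean distance over corresponding body keypoints,

    KD(a, b) = (1/K) * sum_k || a_k - b_k ||,

which folds position *and* orientation into a single metric — two flies whose
bounding boxes overlap almost entirely can still be separated by the
arrangement of their head/thorax/abdomen keypoints.  Matching is done in two
confidence-gated stages: first all detections above a low confidence floor
(default > 0.1) are matched to active tracks under a tight distance gate;
then leftover detections above a higher confidence bar (default > 0.3) are
matched to the still-unassigned tracks under a looser gate, relinking flies
that sprinted or were briefly occluded.  Each stage solves the optimal
one-to-one assignment (Hungarian algorithm) on the KD cost matrix and prunes
matched pairs whose cost exceeds the stage gate afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Detection",
    "Track",
    "TrackerParams",
    "keypoint_distance",
    "build_cost_matrix",
    "solve_assignment",
    "associate_frame",
    "track_session",
    "detections_from_table",
    "TRACK_COLUMNS",
    "KEYPOINT_NAMES",
]

KEYPOINT_NAMES = ("head", "thorax", "abdomen")

TRACK_COLUMNS = [
    "frame", "track_id",
    "head_x", "head_y", "thorax_x", "thorax_y", "abdomen_x", "abdomen_y",
    "matched", "confidence", "sex_label", "truth_id",
]

ACTIVE, LOST, RETIRED = "active", "lost", "retired"


@dataclass
class Detection:
    """One candidate fly in one frame."""

    frame: int
    box: tuple[float, float, float, float]
    keypoints: np.ndarray          # (K, 2)
    confidence: float
    sex_label: str
    truth_id: int | None = None    # evaluation side channel, never used to track

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.keypoints.ndim != 2 or self.keypoints.shape[1] != 2:
            raise ValueError("keypoints must have shape (K, 2)")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError("degenerate bounding box")


@dataclass
class Track:
    """A persistent fly identity."""

    track_id: int
    last_keypoints: np.ndarray
    last_frame: int
    state: str = ACTIVE
    frames_since_match: int = 0
    sex_votes: dict = field(default_factory=lambda: {"male": 0, "female": 0})
    last_detection: "Detection | None" = None  # match in the current frame

    @property
    def live(self) -> bool:
        return self.state in (ACTIVE, LOST)


@dataclass(frozen=True)
class TrackerParams:
    """Two-stage association thresholds.

    The confidence floors come straight from the tracking design (stage 1
    accepts detections with confidence > 0.1, stage 2 requires > 0.3); the
    numeric distance gates are configurable since only their ordering (a low
    then a higher threshold) is prescribed.  ``n_flies`` caps the number of
    live tracks at the known animal count; ``None`` lifts the cap.
    """

    conf_stage1: float = 0.1
    conf_stage2: float = 0.3
    dist_stage1_mm: float = 2.0
    dist_stage2_mm: float = 6.0
    max_lost_frames: int = 30
    n_flies: int | None = None
    stage2_match_lost: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.conf_stage1 < self.conf_stage2 <= 1.0:
            raise ValueError("require 0 <= conf_stage1 < conf_stage2 <= 1")
        if not 0.0 < self.dist_stage1_mm < self.dist_stage2_mm:
            raise ValueError("require 0 < dist_stage1_mm < dist_stage2_mm")
        if self.max_lost_frames < 0:
            raise ValueError("max_lost_frames must be >= 0")


def keypoint_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-keypoint Euclidean distance between two keypoint sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"keypoint sets differ in shape: {a.shape} vs {b.shape}")
    return float(np.mean(np.linalg.norm(a - b, axis=-1)))


def build_cost_matrix(tracks: list[Track], detections: list[Detection]) -> np.ndarray:
    """KD cost of every (track, detection) pair; shape (n_tracks, n_detections)."""
    cost = np.empty((len(tracks), len(detections)))
    for i, t in enumerate(tracks):
        for j, d in enumerate(detections):
            cost[i, j] = keypoint_distance(t.last_keypoints, d.keypoints)
    return cost


def solve_assignment(cost: np.ndarray, gate: float = np.inf) -> set[tuple[int, int]]:
    """Minimum-cost one-to-one assignment, pruned by the distance gate.

    The Hungarian solution is computed on the full matrix first; matched
    pairs whose cost exceeds ``gate`` are then removed, so the retained pairs
    are a subset of the globally optimal assignment.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        return set()
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite")
    rows, cols = linear_sum_assignment(cost)
    return {(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] <= gate}


def _stage(tracks, track_idx, detections, det_idx, gate):
    """Run one association stage; returns matched (track_idx, det_idx) pairs."""
    if not track_idx or not det_idx:
        return set()
    sub = np.empty((len(track_idx), len(det_idx)))
    for a, ti in enumerate(track_idx):
        for b, dj in enumerate(det_idx):
            sub[a, b] = keypoint_distance(tracks[ti].last_keypoints,
                                          detections[dj].keypoints)
    return {(track_idx[a], det_idx[b]) for a, b in solve_assignment(sub, gate)}


def associate_frame(tracks: list[Track], detections: list[Detection],
                    params: TrackerParams, next_id: int | None = None):
    """One tracker update: two-stage matching, lifecycle, track seeding.

    ``tracks`` is updated in place.  Returns ``(tracks, outcomes, next_id)``
    where ``outcomes[j]`` records what happened to detection ``j``
    ("stage1", "stage2", "new", or "unmatched").
    """
    if detections:
        frames = {d.frame for d in detections}
        if len(frames) > 1:
            raise ValueError(f"detections span multiple frames: {sorted(frames)}")
        frame = detections[0].frame
    else:
        frame = None
    if next_id is None:
        next_id = max((t.track_id for t in tracks), default=-1) + 1

    outcomes = ["unmatched"] * len(detections)
    pair_map: dict[int, int] = {}  # track index -> detection index

    # stage 1: low confidence floor, tight gate, active tracks only
    s1_tracks = [i for i, t in enumerate(tracks) if t.state == ACTIVE]
    s1_dets = [j for j, d in enumerate(detections)
               if d.confidence > params.conf_stage1]
    for i, j in _stage(tracks, s1_tracks, detections, s1_dets,
                       params.dist_stage1_mm):
        pair_map[i] = j
        outcomes[j] = "stage1"

    # stage 2: higher confidence bar, looser gate, remaining tracks
    # (including lost ones, to relink after sprints/occlusions)
    s2_states = (ACTIVE, LOST) if params.stage2_match_lost else (ACTIVE,)
    s2_tracks = [i for i, t in enumerate(tracks)
                 if i not in pair_map and t.state in s2_states]
    s2_dets = [j for j, d in enumerate(detections)
               if outcomes[j] == "unmatched" and d.confidence > params.conf_stage2]
    for i, j in _stage(tracks, s2_tracks, detections, s2_dets,
                       params.dist_stage2_mm):
        pair_map[i] = j
        outcomes[j] = "stage2"

    # apply matches and lifecycle updates
    for i, t in enumerate(tracks):
        if t.state == RETIRED:
            continue
        if i in pair_map:
            d = detections[pair_map[i]]
            t.last_keypoints = d.keypoints
            t.last_frame = d.frame
            t.frames_since_match = 0
            t.state = ACTIVE
            t.sex_votes[d.sex_label] = t.sex_votes.get(d.sex_label, 0) + 1
            t.last_detection = d
        else:
            t.frames_since_match += 1
            t.state = LOST
            t.last_detection = None
            if t.frames_since_match > params.max_lost_frames:
                t.state = RETIRED

    # seed new tracks from stage-1-eligible unmatched detections, highest
    # confidence first, up to the configured fly count
    live = sum(1 for t in tracks if t.live)
    seeds = sorted((j for j, d in enumerate(detections)
                    if outcomes[j] == "unmatched"
                    and d.confidence > params.conf_stage1),
                   key=lambda j: (-detections[j].confidence, j))
    for j in seeds:
        if params.n_flies is not None and live >= params.n_flies:
            break
        d = detections[j]
        tracks.append(Track(track_id=next_id, last_keypoints=d.keypoints,
                            last_frame=d.frame,
                            sex_votes={d.sex_label: 1}, last_detection=d))
        next_id += 1
        live += 1
        outcomes[j] = "new"

    return tracks, outcomes, next_id


def detections_from_table(df: pd.DataFrame) -> dict[int, list[Detection]]:
    """Group a detection-stream table into per-frame ``Detection`` lists."""
    by_frame: dict[int, list[Detection]] = {}
    if len(df) == 0:
        return by_frame
    cols = ["frame", "box_xmin", "box_ymin", "box_xmax", "box_ymax",
            "head_x", "head_y", "thorax_x", "thorax_y",
            "abdomen_x", "abdomen_y", "confidence", "sex_label"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"detection table missing columns: {missing}")
    truth = df["truth_id"].to_numpy() if "truth_id" in df.columns else None
    arr = df[cols[:-1]].to_numpy(float)
    labels = df["sex_label"].to_numpy()
    for r in range(len(df)):
        (frame, x0, y0, x1, y1,
         hx, hy, tx, ty, ax, ay, conf) = arr[r]
        det = Detection(
            frame=int(frame), box=(x0, y0, x1, y1),
            keypoints=np.array([[hx, hy], [tx, ty], [ax, ay]]),
            confidence=float(conf), sex_label=str(labels[r]),
            truth_id=None if truth is None else int(truth[r]))
        by_frame.setdefault(int(frame), []).append(det)
    return by_frame


def track_session(detections, params: TrackerParams | None = None,
                  n_frames: int | None = None) -> pd.DataFrame:
    """Track a whole detection stream; one output row per live track per frame.

    ``detections`` may be a detection-stream DataFrame (see
    :data:`courtrack.synthetic_arena.DETECTION_COLUMNS`) or a mapping
    ``frame -> list[Detection]``.  Frames must be non-decreasing; frames with
    no detections still age the tracks.  The output is deterministic given
    the input.
    """
    if params is None:
        params = TrackerParams()
    if isinstance(detections, pd.DataFrame):
        if len(detections) and np.any(np.diff(detections["frame"].to_numpy()) < 0):
            raise ValueError("detection frames must be non-decreasing")
        by_frame = detections_from_table(detections)
    else:
        by_frame = dict(detections)
    if not by_frame and not n_frames:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    last = max(by_frame, default=-1) + 1
    n_frames = last if n_frames is None else max(n_frames, last)

    tracks: list[Track] = []
    next_id = 0
    rows = []
    for frame in range(n_frames):
        dets = by_frame.get(frame, [])
        tracks, outcomes, next_id = associate_frame(tracks, dets, params, next_id)
        for t in tracks:
            if not t.live:
                continue
            matched = t.last_frame == frame
            det = t.last_detection if matched else None
            kp = t.last_keypoints
            rows.append((frame, t.track_id,
                         kp[0, 0], kp[0, 1], kp[1, 0], kp[1, 1], kp[2, 0], kp[2, 1],
                         matched,
                         det.confidence if det else np.nan,
                         det.sex_label if det else "",
                         det.truth_id if det is not None and det.truth_id is not None
                         else -1))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)
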