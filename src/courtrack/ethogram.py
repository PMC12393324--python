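"""Geometric courtship scoring: predicates, bouts, indices, and exclusions.

Courtship is scored purely from pose: a male is courting a female when he is
within 5 mm of her and keeps her inside a 60° frontal cone (facing angle
<= 30° off his heading); close-range "encounters" use the same cone with a
2 mm radius.  From the per-frame predicate the module derives bouts (maximal
runs toward one target), the courtship index (CI, percent of assay time spent
courting, with copulation truncation), the preference index
(PI = (t_A - t_B) / (t_A + t_B)), target-switch counts, stimulus-evoked
pause durations, stimulus-evoked switching probability, and a wing-song mask.

Assay exclusion rules follow the assay designs: single pairings in which the
male copulated within the first 10% of the assay are discarded (later
copulations truncate the assay at that moment), and preference assays in
which the male courted less than 20% of the time are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_arena import BOUT_COLUMNS

__all__ = [
    "AssayResult",
    "facing_angle",
    "is_courting",
    "is_encounter",
    "score_trajectory",
    "extract_bouts",
    "bout_seconds",
    "courtship_index",
    "preference_index",
    "count_switches",
    "pause_after_stimulus",
    "switching_probability",
    "wing_song_mask",
]

COURTSHIP_DIST_MM = 5.0
ENCOUNTER_DIST_MM = 2.0
ARC_DEG = 60.0


@dataclass
class AssayResult:
    """Summary of one scored assay."""

    courtship_index_pct: float = np.nan
    preference_index: float = np.nan
    excluded: bool = False
    exclusion_reason: str = ""
    copulation_frame: int | None = None


def facing_angle(male_pos, male_heading_deg, female_pos):
    """Absolute angle (deg, in [0, 180]) between the male's heading and the
    male-to-female bearing.  NaN where the positions coincide."""
    male_pos = np.asarray(male_pos, dtype=float)
    female_pos = np.asarray(female_pos, dtype=float)
    d = female_pos - male_pos
    dx, dy = d[..., 0], d[..., 1]
    bearing = np.degrees(np.arctan2(dy, dx))
    diff = (bearing - np.asarray(male_heading_deg, dtype=float) + 180.0) % 360.0 - 180.0
    ang = np.abs(diff)
    coincident = (dx == 0) & (dy == 0)
    return np.where(coincident, np.nan, ang) if np.ndim(ang) else \
        (float("nan") if coincident else float(ang))


def is_courting(male_pos, male_heading_deg, female_pos,
                dist_mm: float = COURTSHIP_DIST_MM, arc_deg: float = ARC_DEG):
    """Courtship predicate: closer than ``dist_mm`` with the female inside the
    frontal cone of full width ``arc_deg`` (facing angle <= arc/2)."""
    male_pos = np.asarray(male_pos, dtype=float)
    female_pos = np.asarray(female_pos, dtype=float)
    d = np.linalg.norm(female_pos - male_pos, axis=-1)
    ang = facing_angle(male_pos, male_heading_deg, female_pos)
    return (d < dist_mm) & (ang <= arc_deg / 2.0)


def is_encounter(male_pos, male_heading_deg, female_pos,
                 dist_mm: float = ENCOUNTER_DIST_MM, arc_deg: float = ARC_DEG):
    """Close-range encounter predicate (2 mm radius, same 60° cone)."""
    return is_courting(male_pos, male_heading_deg, female_pos,
                       dist_mm=dist_mm, arc_deg=arc_deg)


def score_trajectory(traj: pd.DataFrame, dist_mm: float = COURTSHIP_DIST_MM,
                     arc_deg: float = ARC_DEG) -> pd.DataFrame:
    """Per-frame courtship flags for a trajectory table.

    Returns a DataFrame (frame, courting, target_id); ``target_id`` is the
    courted female (nearest when several satisfy the predicate), -1 when not
    courting.
    """
    if len(traj) == 0:
        return pd.DataFrame(columns=["frame", "courting", "target_id"])
    male = traj[traj["sex"] == "male"].sort_values("frame")
    if male["fly_id"].nunique() > 1:
        raise ValueError("expected exactly one male in the trajectory")
    females = traj[traj["sex"] == "female"]
    frames = male["frame"].to_numpy()
    mpos = male[["x_mm", "y_mm"]].to_numpy(float)
    mhead = male["heading_deg"].to_numpy(float)

    best_dist = np.full(len(frames), np.inf)
    target = np.full(len(frames), -1, dtype=int)
    for fid, sub in females.groupby("fly_id"):
        sub = sub.set_index("frame").reindex(frames)
        fpos = sub[["x_mm", "y_mm"]].to_numpy(float)
        ok = ~np.isnan(fpos[:, 0])
        d = np.full(len(frames), np.inf)
        d[ok] = np.linalg.norm(fpos[ok] - mpos[ok], axis=-1)
        courting = np.zeros(len(frames), dtype=bool)
        courting[ok] = is_courting(mpos[ok], mhead[ok], fpos[ok],
                                   dist_mm=dist_mm, arc_deg=arc_deg)
        better = courting & (d < best_dist)
        best_dist[better] = d[better]
        target[better] = int(fid)
    return pd.DataFrame({"frame": frames, "courting": target >= 0,
                         "target_id": target})


def extract_bouts(courting, targets, fps: float,
                  min_bout_frames: int = 1) -> pd.DataFrame:
    """Segment per-frame flags into bouts.

    A bout is a maximal run of courting frames with a constant target; runs
    shorter than ``min_bout_frames`` are dropped.  Frames are assumed
    contiguous starting at the first element's frame index 0.
    """
    courting = np.asarray(courting, dtype=bool)
    targets = np.asarray(targets)
    if courting.shape != targets.shape:
        raise ValueError("courting and targets must align")
    rows = []
    start = None
    cur = None
    for f in range(len(courting)):
        lab = targets[f] if courting[f] else None
        if lab != cur:
            if cur is not None and f - start >= min_bout_frames:
                rows.append((start, f, int(cur), (f - start) / fps))
            start, cur = f, lab
    if cur is not None and len(courting) - start >= min_bout_frames:
        rows.append((start, len(courting), int(cur),
                     (len(courting) - start) / fps))
    return pd.DataFrame(rows, columns=BOUT_COLUMNS).astype(
        {"start_frame": int, "end_frame": int, "target_id": int})


def bout_seconds(bouts: pd.DataFrame, fps: float,
                 target_id: int | None = None,
                 end_frame: int | None = None) -> float:
    """Total courting seconds, optionally per target and truncated."""
    if len(bouts) == 0:
        return 0.0
    b = bouts
    if target_id is not None:
        b = b[b["target_id"] == target_id]
    starts = b["start_frame"].to_numpy(float)
    ends = b["end_frame"].to_numpy(float)
    if end_frame is not None:
        ends = np.minimum(ends, end_frame)
    return float(np.clip(ends - starts, 0, None).sum() / fps)


def courtship_index(bouts: pd.DataFrame, assay_frames: int, fps: float,
                    copulation_frame: int | None = None) -> AssayResult:
    """Courtship index in percent: total courting time / assay time * 100.

    A copulation later than 10% into the assay truncates both the denominator
    and the bouts at the copulation frame; a copulation within the first 10%
    excludes the assay outright.
    """
    if assay_frames <= 0:
        raise ValueError("assay_frames must be > 0")
    res = AssayResult(copulation_frame=copulation_frame)
    end = assay_frames
    if copulation_frame is not None:
        if copulation_frame <= 0.1 * assay_frames:
            res.excluded = True
            res.exclusion_reason = "copulated within first 10% of assay"
            return res
        end = min(copulation_frame, assay_frames)
    t_court = bout_seconds(bouts, fps, end_frame=end)
    res.courtship_index_pct = 100.0 * t_court / (end / fps)
    return res


def preference_index(bouts_a: pd.DataFrame, bouts_b: pd.DataFrame,
                     assay_frames: int, fps: float) -> AssayResult:
    """PI = (t_A - t_B) / (t_A + t_B), in [-1, 1].

    Undefined (NaN) when the male never courted; flagged excluded when total
    courtship covers less than 20% of the assay.
    """
    if assay_frames <= 0:
        raise ValueError("assay_frames must be > 0")
    t_a = bout_seconds(bouts_a, fps)
    t_b = bout_seconds(bouts_b, fps)
    total = t_a + t_b
    res = AssayResult()
    if total < 0.2 * assay_frames / fps:
        res.excluded = True
        res.exclusion_reason = "courted less than 20% of preference assay"
    if total > 0:
        res.preference_index = (t_a - t_b) / total
    return res


def count_switches(bouts: pd.DataFrame) -> int:
    """Number of consecutive bout pairs whose targets differ."""
    if len(bouts) < 2:
        return 0
    t = bouts.sort_values("start_frame")["target_id"].to_numpy()
    return int(np.sum(t[1:] != t[:-1]))


def pause_after_stimulus(bouts: pd.DataFrame, stimulus_onset_frame: int,
                         window_frames: int, fps: float) -> float:
    """Seconds from stimulus onset until courtship resumes.

    Requires the male to have been courting at the onset or within the
    preceding second (otherwise NaN).  If a bout spans the onset the pause is
    0; if courtship never resumes within the window the value is censored at
    the window length.
    """
    if len(bouts) == 0:
        return float("nan")
    starts = bouts["start_frame"].to_numpy()
    ends = bouts["end_frame"].to_numpy()
    onset = stimulus_onset_frame
    pre_ok = np.any((starts <= onset) & (ends > onset - fps))
    if not pre_ok:
        return float("nan")
    covering = (starts <= onset) & (ends > onset)
    if np.any(covering):
        return 0.0
    post = starts[(starts > onset) & (starts < onset + window_frames)]
    if len(post) == 0:
        return window_frames / fps
    return float((post.min() - onset) / fps)


def switching_probability(bouts: pd.DataFrame, stimulus_onsets,
                          window_frames: int) -> float:
    """Fraction of stimuli after which the male resumed courtship of a
    *different* female than the one he was courting before the stimulus.

    Stimuli without a defined pre-stimulus target, or without any resumption
    inside the window, drop out of the denominator; NaN if none remain.
    """
    if len(bouts) == 0:
        return float("nan")
    b = bouts.sort_values("start_frame")
    starts = b["start_frame"].to_numpy()
    ends = b["end_frame"].to_numpy()
    targets = b["target_id"].to_numpy()
    n, switched = 0, 0
    for onset in stimulus_onsets:
        pre = np.flatnonzero(starts <= onset)
        if len(pre) == 0:
            continue
        # pre-stimulus target: the last bout begun at or before the onset
        pre_target = targets[pre[-1]]
        post = np.flatnonzero((ends > onset) & (starts < onset + window_frames))
        if len(post) == 0:
            continue
        post_target = targets[post[0]]
        n += 1
        switched += int(post_target != pre_target)
    return switched / n if n else float("nan")


def wing_song_mask(wing_left_deg, wing_right_deg,
                   threshold_deg: float = 30.0):
    """True where either wing is extended at or beyond the threshold angle."""
    l = np.abs(np.asarray(wing_left_deg, dtype=float))
    r = np.abs(np.asarray(wing_right_deg, dtype=float))
    return np.maximum(l, r) >= threshold_deg
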