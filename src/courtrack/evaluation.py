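"""Scoring tracker output against the simulator's ground-truth identities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TrackingErrors", "tracking_errors", "male_identity_accuracy"]


@dataclass
class TrackingErrors:
    """Identity-error tallies for one tracked session.

    ``id_switches`` counts transitions where a truth fly's matched track id
    changes to an id that previously followed a *different* fly (a swap);
    ``fragmentations`` counts changes to a fresh or unaffiliated id (a track
    lost and re-seeded).
    """

    id_switches: int
    fragmentations: int
    frames_evaluated: int


def _per_frame_match(track_table: pd.DataFrame, truth: pd.DataFrame,
                     tol_mm: float):
    """For each (frame, track) row, the truth fly whose centroid is nearest
    the track's thorax (within ``tol_mm``), as parallel arrays."""
    tr = truth.pivot_table(index="frame", columns="fly_id",
                           values=["x_mm", "y_mm"])
    fly_ids = tr["x_mm"].columns.to_numpy()
    tx = tr["x_mm"].to_numpy()
    ty = tr["y_mm"].to_numpy()
    frame_index = tr.index.to_numpy()
    pos = {f: i for i, f in enumerate(frame_index)}

    frames = track_table["frame"].to_numpy()
    rows = np.array([pos.get(f, -1) for f in frames])
    ok = rows >= 0
    thx = track_table["thorax_x"].to_numpy(float)
    thy = track_table["thorax_y"].to_numpy(float)
    matched_fly = np.full(len(track_table), -1, dtype=int)
    if ok.any():
        d = np.sqrt((tx[rows[ok]] - thx[ok, None]) ** 2
                    + (ty[rows[ok]] - thy[ok, None]) ** 2)
        best = np.argmin(d, axis=1)
        bestd = d[np.arange(len(best)), best]
        sel = bestd <= tol_mm
        out = np.full(ok.sum(), -1, dtype=int)
        out[sel] = fly_ids[best[sel]]
        matched_fly[ok] = out
    return matched_fly


def tracking_errors(track_table: pd.DataFrame, truth: pd.DataFrame,
                    tol_mm: float = 3.0) -> TrackingErrors:
    """Count identity switches and fragmentations against ground truth.

    Each track row is attributed to the nearest truth fly (within
    ``tol_mm``); for every truth fly the sequence of track ids following it
    is then scanned for changes.
    """
    if len(track_table) == 0:
        return TrackingErrors(0, 0, 0)
    if "matched" in track_table.columns:
        # coasting (lost) tracks repeat stale keypoints; only rows backed by
        # a detection say anything about who the track is following
        track_table = track_table[track_table["matched"].astype(bool)]
        track_table = track_table.reset_index(drop=True)
    matched_fly = _per_frame_match(track_table, truth, tol_mm)
    frames = track_table["frame"].to_numpy()
    tids = track_table["track_id"].to_numpy()

    id_switches = 0
    fragmentations = 0
    last_track_of_fly: dict[int, int] = {}  # fly -> track most recently on it
    last_fly_of_track: dict[int, int] = {}  # track -> fly it last followed
    order = np.lexsort((tids, frames))
    for i in order:
        fly = matched_fly[i]
        if fly < 0:
            continue
        tid = int(tids[i])
        prev_tid = last_track_of_fly.get(fly)
        if prev_tid is not None and prev_tid != tid:
            # the fly changed tracks: a swap if its new track had been
            # following a different fly, a fragmentation otherwise
            if last_fly_of_track.get(tid, fly) != fly:
                id_switches += 1
            else:
                fragmentations += 1
        last_track_of_fly[fly] = tid
        last_fly_of_track[tid] = fly
    n_frames = len(np.unique(frames))
    return TrackingErrors(id_switches, fragmentations, n_frames)


def male_identity_accuracy(track_table: pd.DataFrame,
                           roles: pd.DataFrame,
                           truth: pd.DataFrame,
                           male_fly_id: int = 0,
                           tol_mm: float = 2.5) -> float:
    """Fraction of frames on which the guarded male identity truly sits on
    the male fly.

    A frame counts as correct when the designated male track's thorax lies
    within ``tol_mm`` (about one body length) of the ground-truth male
    position — during a merged-detection occlusion the shared track sits
    between the two flies and still qualifies.  Frames before any male
    designation, or where the male track has no row, count as wrong.
    """
    male_truth = truth[truth["fly_id"] == male_fly_id]
    mt = male_truth.set_index("frame")[["x_mm", "y_mm"]]
    key = (track_table["frame"].astype(int).astype(str) + ":"
           + track_table["track_id"].astype(int).astype(str))
    tpos = dict(zip(key, zip(track_table["thorax_x"], track_table["thorax_y"])))
    n = 0
    good = 0
    for f, tid in zip(roles["frame"].to_numpy(), roles["male_track_id"].to_numpy()):
        if f not in mt.index:
            continue
        n += 1
        p = tpos.get(f"{f}:{tid}")
        if p is None:
            continue
        gx, gy = mt.loc[f].to_numpy()
        if np.hypot(p[0] - gx, p[1] - gy) <= tol_mm:
            good += 1
    return good / n if n else float("nan")
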