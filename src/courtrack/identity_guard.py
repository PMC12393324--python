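"""Male/female identity maintenance on top of the tracker.

The tracker occasionally exchanges which fly a track follows, typically when
a courting pair occludes.  In a one-male session the detector's per-frame sex
labels carry enough signal to notice and repair this: the guard keeps a
running, exponentially decaying tally of sex labels per track, records which
track currently holds the male identity, and applies two corrections:

* **swap correction** — if the male label sits on a non-canonical track for
  ``n_consecutive`` frames in a row, the two tracks are deemed to have
  exchanged flies and their identities (and vote histories) are swapped back;
* **periodic reassignment** — every ``period`` frames (default 120) the male
  identity is re-derived from the accumulated sex votes, catching slow drifts
  that never produce a long consecutive divergence.

Frames in which no unambiguous male-labeled track exists (male undetected,
or two detections both labeled male) neither increment nor reset the
divergence counter: absence of the label is not evidence of a swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GuardParams",
    "SexRecord",
    "update_sex_record",
    "correct_swap",
    "periodic_reassign",
    "assign_roles",
]


@dataclass(frozen=True)
class GuardParams:
    """Identity-guard thresholds.

    ``n_consecutive`` (frames of persistent divergence before a swap
    correction, default 15 = 0.5 s at 30 Hz), ``period`` (frames between
    vote-based reassignments, default 120), and ``vote_half_life`` (frames
    over which old sex votes decay to half weight, so stale labels cannot
    outvote recent ones).
    """

    n_consecutive: int = 15
    period: int = 120
    vote_half_life: float = 300.0

    def __post_init__(self) -> None:
        if self.n_consecutive < 1:
            raise ValueError("n_consecutive must be >= 1")
        if self.period < 1:
            raise ValueError("period must be >= 1")
        if self.vote_half_life <= 0:
            raise ValueError("vote_half_life must be > 0")


@dataclass
class SexRecord:
    """Running sex-label bookkeeping for a one-male session."""

    male_track_id: int | None = None
    consecutive_divergence: int = 0
    divergent_track_id: int | None = None
    frame: int = -1
    male_history: list = field(default_factory=list)   # (frame, track_id)
    # per-track decayed vote weights: track_id -> [male_weight, female_weight]
    votes: dict = field(default_factory=dict)

    def male_share(self, track_id: int) -> float:
        m, f = self.votes.get(track_id, (0.0, 0.0))
        tot = m + f
        return m / tot if tot > 0 else np.nan


def update_sex_record(record: SexRecord, frame: int,
                      labels: dict[int, str],
                      params: GuardParams | None = None) -> SexRecord:
    """Fold one frame of per-track sex labels into the record.

    ``labels`` maps track_id -> detected sex label for tracks matched in this
    frame; unmatched tracks are simply absent.  An empty mapping advances the
    frame counter and leaves everything else unchanged.
    """
    if params is None:
        params = GuardParams()
    record.frame = frame
    decay = 0.5 ** (1.0 / params.vote_half_life)
    for tid in record.votes:
        record.votes[tid][0] *= decay
        record.votes[tid][1] *= decay
    for tid, label in labels.items():
        w = record.votes.setdefault(tid, [0.0, 0.0])
        w[0 if label == "male" else 1] += 1.0

    male_tracks = [tid for tid, lab in labels.items() if lab == "male"]
    if record.male_track_id is None and len(male_tracks) == 1:
        record.male_track_id = male_tracks[0]
    elif len(male_tracks) == 1:
        tid = male_tracks[0]
        if tid == record.male_track_id:
            record.consecutive_divergence = 0
            record.divergent_track_id = None
        else:
            record.consecutive_divergence += 1
            record.divergent_track_id = tid
    # zero or multiple male labels: ambiguous, divergence unchanged
    record.male_history.append((frame, record.male_track_id))
    return record


def correct_swap(record: SexRecord, n_consecutive: int):
    """Swap identities once divergence has persisted long enough.

    Returns ``(record, event)`` where ``event`` is ``None`` or a dict
    describing the correction.  The vote tallies of the two tracks are
    exchanged along with their identities, since the correction asserts the
    tracks have been following each other's fly.
    """
    if n_consecutive < 1:
        raise ValueError("n_consecutive must be >= 1")
    if (record.consecutive_divergence < n_consecutive
            or record.divergent_track_id is None):
        return record, None
    old_male = record.male_track_id
    usurper = record.divergent_track_id
    record.male_track_id = usurper
    va = record.votes.setdefault(old_male, [0.0, 0.0])
    vb = record.votes.setdefault(usurper, [0.0, 0.0])
    record.votes[old_male], record.votes[usurper] = vb, va
    record.consecutive_divergence = 0
    record.divergent_track_id = None
    event = {"frame": record.frame, "type": "swap_correction",
             "from_track": old_male, "to_track": usurper}
    return record, event


def periodic_reassign(record: SexRecord, frame: int, period: int,
                      live_tracks=None):
    """Re-derive the male identity from accumulated votes every ``period`` frames.

    ``live_tracks`` optionally restricts candidates to currently live track
    ids.  Returns ``(record, event)``.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    if frame == 0 or frame % period != 0:
        return record, None
    candidates = record.votes.keys() if live_tracks is None else \
        [t for t in record.votes if t in set(live_tracks)]
    best, best_share = None, -1.0
    for tid in sorted(candidates):
        share = record.male_share(tid)
        if not np.isnan(share) and share > best_share:
            best, best_share = tid, share
    if best is None or best == record.male_track_id:
        return record, None
    event = {"frame": frame, "type": "periodic_reassign",
             "from_track": record.male_track_id, "to_track": best}
    record.male_track_id = best
    record.consecutive_divergence = 0
    record.divergent_track_id = None
    return record, event


def assign_roles(track_table: pd.DataFrame,
                 params: GuardParams | None = None):
    """Run the guard over a tracked session.

    Consumes a track table (see :data:`courtrack.kd_tracker.TRACK_COLUMNS`)
    and returns ``(roles, events)`` where ``roles`` is a DataFrame with one
    row per frame giving the track id holding the male identity, and
    ``events`` lists the corrections applied.
    """
    if params is None:
        params = GuardParams()
    record = SexRecord()
    events: list[dict] = []
    rows = []
    if len(track_table) == 0:
        return pd.DataFrame(columns=["frame", "male_track_id"]), events

    frames = track_table["frame"].to_numpy()
    tids = track_table["track_id"].to_numpy()
    matched = track_table["matched"].to_numpy(bool)
    labels = track_table["sex_label"].to_numpy()
    n_frames = int(frames.max()) + 1
    order = np.argsort(frames, kind="mergesort")
    bounds = np.searchsorted(frames[order], np.arange(n_frames + 1))
    live_by_frame = None
    for f in range(n_frames):
        sl = order[bounds[f]:bounds[f + 1]]
        frame_labels = {int(tids[i]): str(labels[i]) for i in sl
                        if matched[i] and labels[i] in ("male", "female")}
        live = [int(tids[i]) for i in sl]
        update_sex_record(record, f, frame_labels, params)
        record, ev = correct_swap(record, params.n_consecutive)
        if ev:
            events.append(ev)
        record, ev = periodic_reassign(record, f, params.period, live)
        if ev:
            events.append(ev)
        rows.append((f, -1 if record.male_track_id is None
                     else record.male_track_id))
    roles = pd.DataFrame(rows, columns=["frame", "male_track_id"])
    return roles, events
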