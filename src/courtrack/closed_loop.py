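"""Optogenetic stimulation logic: protocol schedulers and the closed-loop trigger.

Open-loop protocols reproduce the published stimulation schedules exactly in
frames: *chronic* activation is two minutes of baseline followed by a single
30 s constant-LED episode and a one-minute post-baseline; *brief* activation
repeats five times a 2 s pulse train (10 Hz, 50% duty cycle) followed by a
one-minute baseline.

The closed-loop trigger delivers a 500 ms constant pulse whenever the male is
closer than 2 mm to an arbitrarily designated "fictive heterospecific" female
and keeps her within a 60° frontal arc — the encounter predicate of the
ethogram module.  :func:`run_closed_loop` couples this trigger to the
behaviorally responsive simulated male: an LED episode aborts his pursuit
with probability ``p_abort_on_stimulus``, after which he re-targets on his
next initiation, biasing his courtship toward the control female exactly as
in the live closed-loop preference assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ethogram
from .identity_guard import GuardParams, SexRecord, correct_swap, \
    periodic_reassign, update_sex_record
from .kd_tracker import TrackerParams, associate_frame, detections_from_table
from .synthetic_arena import (ArenaConfig, ArenaSimulator, BehaviorParams,
                              NoiseParams, render_detections)

__all__ = [
    "TriggerParams",
    "STIMULUS_COLUMNS",
    "trigger_decision",
    "schedule_protocol",
    "run_closed_loop",
    "closed_loop_exclusion",
    "closed_loop_preference",
]

STIMULUS_COLUMNS = ["onset_frame", "offset_frame", "mode",
                    "rate_hz", "duty_fraction"]

_BASELINE_S = 120.0     # two minutes of baseline before any stimulation
_CHRONIC_ON_S = 30.0
_BRIEF_ON_S = 2.0
_BRIEF_OFF_S = 60.0
_BRIEF_REPEATS = 5
_BRIEF_RATE_HZ = 10.0
_BRIEF_DUTY = 0.5


@dataclass(frozen=True)
class TriggerParams:
    """Closed-loop trigger geometry and pulse timing."""

    dist_mm: float = 2.0
    arc_deg: float = 60.0
    pulse_ms: float = 500.0
    designated_female: int = 1
    refractory_ms: float = 500.0

    def __post_init__(self) -> None:
        for name in ("dist_mm", "arc_deg", "pulse_ms", "refractory_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def trigger_decision(male_pos, male_heading_deg, designated_female_pos,
                     params: TriggerParams) -> bool:
    """True when the male satisfies the proximity/orientation trigger rule."""
    return bool(ethogram.is_courting(male_pos, male_heading_deg,
                                     designated_female_pos,
                                     dist_mm=params.dist_mm,
                                     arc_deg=params.arc_deg))


def schedule_protocol(kind: str, fps: float) -> pd.DataFrame:
    """Open-loop stimulus schedule in exact frame arithmetic.

    ``chronic``: one 30 s episode starting at 120 s.  ``brief``: five 2 s
    pulse-train episodes (10 Hz, 50% duty), the first at 120 s, subsequent
    onsets separated by 62 s (2 s on + 60 s baseline).
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    rows = []
    if kind == "chronic":
        on = int(round(_BASELINE_S * fps))
        rows.append((on, on + int(round(_CHRONIC_ON_S * fps)),
                     "chronic", np.nan, np.nan))
    elif kind == "brief":
        period = _BRIEF_ON_S + _BRIEF_OFF_S
        for k in range(_BRIEF_REPEATS):
            on = int(round((_BASELINE_S + k * period) * fps))
            rows.append((on, on + int(round(_BRIEF_ON_S * fps)),
                         "brief", _BRIEF_RATE_HZ, _BRIEF_DUTY))
    else:
        raise ValueError(f"unknown protocol kind: {kind!r}")
    return pd.DataFrame(rows, columns=STIMULUS_COLUMNS)


class _TrackedPoseSource:
    """Online tracker+guard reading the male and designated-female poses from
    tracks rather than ground truth, mirroring the real-time system."""

    def __init__(self, arena: ArenaConfig, trigger: TriggerParams,
                 noise: NoiseParams | None,
                 tracker: TrackerParams | None,
                 guard: GuardParams | None, seed: int):
        self.arena = arena
        self.noise = noise if noise is not None else NoiseParams(
            keypoint_jitter_mm=0.0, dropout_base=0.0, dropout_speed_gain=0.0,
            sexlabel_error=0.0, occlusion_dist_mm=0.0,
            conf_low=1.0, conf_high=1.0, seed=seed)
        self.rng = np.random.default_rng(seed)
        self.tracker = tracker if tracker is not None else TrackerParams(
            n_flies=1 + arena.n_females)
        self.guard = guard if guard is not None else GuardParams()
        self.record = SexRecord()
        self.tracks: list = []
        self.next_id = 0
        self.designated_track: int | None = None
        self.designated_truth = trigger.designated_female

    def poses(self, sim: ArenaSimulator, frame: int):
        """Advance the tracker one frame.

        Returns ``(male_pos, male_heading_deg, designated_pos)`` from the
        tracked keypoints (male heading taken from his head-thorax axis), or
        ``None`` while either identity is unavailable.
        """
        truth = sim.current_frame_table()
        det_df = render_detections(truth, self.noise, fps=self.arena.fps,
                                   rng=self.rng)
        dets = detections_from_table(det_df).get(frame, [])
        self.tracks, _, self.next_id = associate_frame(
            self.tracks, dets, self.tracker, self.next_id)

        labels = {t.track_id: t.last_detection.sex_label
                  for t in self.tracks
                  if t.live and t.last_frame == frame
                  and t.last_detection is not None}
        update_sex_record(self.record, frame, labels, self.guard)
        self.record, _ = correct_swap(self.record, self.guard.n_consecutive)
        live_ids = [t.track_id for t in self.tracks if t.live]
        self.record, _ = periodic_reassign(self.record, frame,
                                           self.guard.period, live_ids)

        by_id = {t.track_id: t for t in self.tracks if t.live}
        if self.designated_track is None:
            # designate once, when every fly has a live track: the track
            # nearest the chosen female's position (the experimenter's click)
            if len(by_id) == 1 + self.arena.n_females:
                fem = truth[truth["fly_id"] == self.designated_truth].iloc[0]
                fpos = np.array([fem["x_mm"], fem["y_mm"]])
                cand = [t for t in by_id.values()
                        if t.track_id != self.record.male_track_id]
                if cand:
                    self.designated_track = min(
                        cand, key=lambda t: float(np.linalg.norm(
                            t.last_keypoints[1] - fpos))).track_id
        male = by_id.get(self.record.male_track_id)
        desig = by_id.get(self.designated_track)
        if male is None or desig is None:
            return None
        head, thorax = male.last_keypoints[0], male.last_keypoints[1]
        heading = float(np.degrees(np.arctan2(head[1] - thorax[1],
                                              head[0] - thorax[0])))
        return thorax, heading, desig.last_keypoints[1]


def run_closed_loop(arena: ArenaConfig, behavior: BehaviorParams,
                    trigger: TriggerParams | None = None,
                    noise: NoiseParams | None = None,
                    use_tracking: bool = False,
                    tracker: TrackerParams | None = None,
                    guard: GuardParams | None = None):
    """Virtual closed-loop preference experiment.

    The simulator advances frame by frame; whenever the trigger rule holds
    (and the refractory gap since the last episode has elapsed) a constant
    ``pulse_ms`` LED episode is scheduled starting at the next frame.  While
    an episode is active the simulated male aborts his pursuit with
    probability ``behavior.p_abort_on_stimulus``.

    By default the trigger reads ground-truth poses.  With
    ``use_tracking=True`` it instead reads poses from the online
    tracker+guard pipeline (optionally under detector noise), mirroring the
    real system; on noiseless sessions both paths produce identical logs.

    Returns ``(trajectory_table, bout_table, stimulus_log)``.
    """
    if arena.n_females != 2:
        raise ValueError("the closed-loop preference assay uses two females")
    if trigger is None:
        trigger = TriggerParams()
    if not 1 <= trigger.designated_female <= arena.n_females:
        raise ValueError("designated_female must be one of the session's females")

    fps = arena.fps
    pulse_frames = max(1, int(round(trigger.pulse_ms * fps / 1000.0)))
    refractory_frames = int(round(trigger.refractory_ms * fps / 1000.0))
    n_frames = arena.n_frames

    sim = ArenaSimulator(arena, behavior)
    source = (_TrackedPoseSource(arena, trigger, noise, tracker, guard,
                                 seed=behavior.seed + 1)
              if use_tracking else None)

    episodes: list[tuple[int, int]] = []
    episode_end = -1          # current episode's offset frame (exclusive)
    last_offset = -10**9      # offset of the most recent episode
    pending_onset = -1

    for frame in range(n_frames):
        if frame == pending_onset:
            episode_end = frame + pulse_frames
            episodes.append((frame, episode_end))
            last_offset = episode_end
            pending_onset = -1
        stim_active = frame < episode_end
        sim.step(stim_active=stim_active)

        if use_tracking:
            pose = source.poses(sim, frame)
            if pose is None:
                continue
            male_pos, male_heading, desig_pos = pose
        else:
            male_pos = np.array([sim._x[0], sim._y[0]])
            male_heading = sim._heading[0]
            desig_pos = np.array([sim._x[trigger.designated_female],
                                  sim._y[trigger.designated_female]])

        if (not stim_active and pending_onset < 0
                and frame + 1 - last_offset >= refractory_frames
                and frame + 1 + pulse_frames <= n_frames
                and trigger_decision(male_pos, male_heading, desig_pos,
                                     trigger)):
            pending_onset = frame + 1

    log = pd.DataFrame(
        [(on, off, "closed_loop", np.nan, np.nan) for on, off in episodes],
        columns=STIMULUS_COLUMNS)
    return sim.trajectory_table(), sim.bout_table(), log


def closed_loop_exclusion(copulation_frame: int | None, assay_frames: int,
                          min_fraction: float = 0.2):
    """Copulation rule for the closed-loop assay.

    Returns ``(excluded, end_frame)``: a copulation earlier than
    ``min_fraction`` of the assay discards the trial; a later one truncates
    analysis at the copulation frame; no copulation keeps the full assay.
    """
    if assay_frames <= 0:
        raise ValueError("assay_frames must be > 0")
    if copulation_frame is None:
        return False, assay_frames
    if copulation_frame < min_fraction * assay_frames:
        return True, None
    return False, min(copulation_frame, assay_frames)


def closed_loop_preference(bouts: pd.DataFrame, arena: ArenaConfig,
                           trigger: TriggerParams) -> "ethogram.AssayResult":
    """Preference index with the *control* (non-designated) female as A.

    A positive value therefore means the male preferred the female that
    never triggered inhibitory stimulation.
    """
    females = set(range(1, 1 + arena.n_females))
    control = sorted(females - {trigger.designated_female})[0]
    bouts_control = bouts[bouts["target_id"] == control]
    bouts_desig = bouts[bouts["target_id"] == trigger.designated_female]
    return ethogram.preference_index(bouts_control, bouts_desig,
                                     arena.n_frames, arena.fps)
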