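"""Synthetic courtship-arena sessions and their corruption into detection streams.

The simulator produces ground-truth trajectories and courtship-bout labels for
one male and one or two females in a circular arena (default 38 mm diameter,
30 Hz).  Male behavior follows a two-state semi-Markov model: he alternates
between roaming (random walk) and courting a chosen female (close pursuit),
with exponentially distributed dwell times.  At each courtship initiation he
may switch his target female, and an active optogenetic stimulus can abort his
pursuit — the behavioral hooks exercised by the closed-loop engine.

:func:`render_detections` then degrades a ground-truth trajectory into the
kind of per-frame detection stream a pose detector emits: jittered keypoints,
speed-dependent dropouts, sex-label errors, graded confidence scores, and
merged detections when two flies are close enough to occlude each other.  The
true identity behind every detection is kept in ``truth_*`` side-channel
columns so trackers can be scored against it.

Conventions: millimetres, origin at the arena centre, y up; headings in
degrees counter-clockwise from +x, stored in [0, 360); frames 0-based;
intervals half-open [start, end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ArenaConfig",
    "BehaviorParams",
    "NoiseParams",
    "ArenaSimulator",
    "simulate_session",
    "render_detections",
    "pose_to_keypoints",
    "MALE_BODY_LENGTH_MM",
    "FEMALE_BODY_LENGTH_MM",
    "TRAJECTORY_COLUMNS",
    "BOUT_COLUMNS",
    "DETECTION_COLUMNS",
]

# Body sizes: females are slightly larger than males so that sex is in
# principle recoverable from geometry alone.
MALE_BODY_LENGTH_MM = 2.0
FEMALE_BODY_LENGTH_MM = 2.5

# Pursuit geometry (internal, not exposed as parameters): the courting male
# holds station just behind the female, inside the 2 mm "encounter" radius
# often enough to exercise proximity-triggered stimulation.
_FOLLOW_DIST_MM = 1.8          # distance the courting male tries to hold
# the labeled bout begins exactly when the courtship predicate first holds
# (the approach leg is oriented at the female, so the 60° cone is satisfied
# and the predicate switches on at the 5 mm radius)
_COURT_ENTRY_DIST_MM = 5.0
_COURT_HEADING_JITTER_DEG = 4.0
_FEMALE_SPEED_MMS = 4.0        # slow random walk; see docs/methods.md
_FEMALE_TURN_DEG_SQRT_S = 40.0
_ROAM_TURN_DEG_SQRT_S = 80.0
_ROAM_AVOID_DIST_MM = 6.0
_COLLISION_AVOID_MM = 2.2
_WALL_MARGIN_MM = 1.0
_WING_MAX_DEG = 45.0
_WING_FREQ_HZ = 2.5
_BOX_PAD_MM = 0.5

TRAJECTORY_COLUMNS = [
    "frame", "fly_id", "x_mm", "y_mm", "heading_deg",
    "wing_left_deg", "wing_right_deg", "sex",
]
BOUT_COLUMNS = ["start_frame", "end_frame", "target_id", "duration_s"]
DETECTION_COLUMNS = [
    "frame", "box_xmin", "box_ymin", "box_xmax", "box_ymax",
    "head_x", "head_y", "thorax_x", "thorax_y", "abdomen_x", "abdomen_y",
    "confidence", "sex_label", "truth_id", "truth_merged_with",
]


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _check_pos(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class ArenaConfig:
    """Circular assay chamber and recording parameters."""

    diameter_mm: float = 38.0
    fps: float = 30.0
    duration_s: float = 600.0
    n_females: int = 1

    def __post_init__(self) -> None:
        _check_pos("diameter_mm", self.diameter_mm)
        _check_pos("fps", self.fps)
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")
        if self.n_females not in (1, 2):
            raise ValueError("n_females must be 1 or 2")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass(frozen=True)
class BehaviorParams:
    """Stochastic male behavior model.

    ``p_initiate`` is the per-second probability of starting courtship once
    the post-disengagement pause has elapsed; ``p_switch`` the probability of
    changing target female at each initiation; ``p_abort_on_stimulus`` the
    probability that an LED episode aborts an ongoing pursuit.  Bout and
    pause dwell times are exponential with the given means (seconds).
    """

    p_initiate: float = 0.5
    p_switch: float = 0.8
    p_abort_on_stimulus: float = 1.0
    mean_bout_s: float = 20.0
    mean_pause_s: float = 5.0
    speed_courting_mms: float = 10.0
    speed_roaming_mms: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob("p_initiate", self.p_initiate)
        _check_prob("p_switch", self.p_switch)
        _check_prob("p_abort_on_stimulus", self.p_abort_on_stimulus)
        for name in ("mean_bout_s", "mean_pause_s",
                     "speed_courting_mms", "speed_roaming_mms"):
            _check_pos(name, getattr(self, name))


@dataclass(frozen=True)
class NoiseParams:
    """Detector failure model applied by :func:`render_detections`."""

    keypoint_jitter_mm: float = 0.1
    dropout_base: float = 0.02
    dropout_speed_gain: float = 0.002  # extra miss probability per mm/s
    sexlabel_error: float = 0.05
    occlusion_dist_mm: float = 1.5
    conf_low: float = 0.2
    conf_high: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.keypoint_jitter_mm < 0:
            raise ValueError("keypoint_jitter_mm must be >= 0")
        _check_prob("dropout_base", self.dropout_base)
        if self.dropout_speed_gain < 0:
            raise ValueError("dropout_speed_gain must be >= 0")
        _check_prob("sexlabel_error", self.sexlabel_error)
        if self.occlusion_dist_mm < 0:
            raise ValueError("occlusion_dist_mm must be >= 0")
        if not self.conf_low <= self.conf_high:
            raise ValueError("conf_low must be <= conf_high")
        _check_prob("conf_low", self.conf_low)
        _check_prob("conf_high", self.conf_high)


def pose_to_keypoints(x_mm, y_mm, heading_deg, body_length_mm):
    """Head/thorax/abdomen keypoints for a pose.

    The thorax sits at the centroid, the head half a body length along the
    heading, the abdomen half a body length behind.  Accepts scalars or
    equal-shaped arrays; returns an array of shape ``(..., 3, 2)`` ordered
    head, thorax, abdomen.
    """
    body_length_mm = np.asarray(body_length_mm, dtype=float)
    if np.any(body_length_mm <= 0):
        raise ValueError("body_length_mm must be > 0")
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    theta = np.deg2rad(np.asarray(heading_deg, dtype=float))
    half = body_length_mm / 2.0
    dx, dy = half * np.cos(theta), half * np.sin(theta)
    thorax = np.stack([x, y], axis=-1)
    offset = np.stack([dx, dy], axis=-1)
    return np.stack([thorax + offset, thorax, thorax - offset], axis=-2)


# ---------------------------------------------------------------------------
# Ground-truth simulator
# ---------------------------------------------------------------------------

_ROAM, _APPROACH, _COURT = 0, 1, 2


class ArenaSimulator:
    """Frame-stepped ground-truth simulator.

    Fly 0 is the male; flies ``1 .. n_females`` are females.  Call
    :meth:`step` once per frame, optionally flagging an active optogenetic
    stimulus; collect results with :meth:`trajectory_table` and
    :meth:`bout_table`.
    """

    def __init__(self, arena: ArenaConfig, behavior: BehaviorParams,
                 rng: np.random.Generator | None = None):
        self.arena = arena
        self.behavior = behavior
        self.rng = np.random.default_rng(behavior.seed) if rng is None else rng
        self.dt = 1.0 / arena.fps
        self.frame = 0
        self._wall_r = max(arena.radius_mm - _WALL_MARGIN_MM, 1.0)

        r0 = max(self._wall_r - 2.0, 0.5)
        n = 1 + arena.n_females
        rad = r0 * np.sqrt(self.rng.uniform(0, 1, n))
        ang = self.rng.uniform(0, 2 * math.pi, n)
        self._x = rad * np.cos(ang)
        self._y = rad * np.sin(ang)
        self._heading = self.rng.uniform(0, 360, n)

        self._state = _ROAM
        self._target = -1          # current target female id (-1 none)
        self._last_target = -1
        self._pause_frames = self._draw_frames(behavior.mean_pause_s)
        self._bout_frames = 0
        self._bout_t0 = 0.0        # session time of bout start, for wing phase
        self._wing_side = 0
        self._prev_stim = False
        # per-frame probability equivalent of the per-second initiation rate
        p = behavior.p_initiate
        self._p_init_frame = 1.0 if p >= 1.0 else 1.0 - (1.0 - p) ** self.dt

        self._rows: list[tuple] = []
        self._labels: list[int] = []   # courted target per frame, -1 if none

    # -- helpers -----------------------------------------------------------

    def _draw_frames(self, mean_s: float) -> int:
        return max(1, int(round(self.rng.exponential(mean_s) / self.dt)))

    def _clamp_to_wall(self, i: int) -> bool:
        r = math.hypot(self._x[i], self._y[i])
        if r > self._wall_r:
            s = self._wall_r / r
            self._x[i] *= s
            self._y[i] *= s
            return True
        return False

    def _bearing_to(self, i: int, j: int) -> float:
        return math.degrees(math.atan2(self._y[j] - self._y[i],
                                       self._x[j] - self._x[i]))

    def _dist(self, i: int, j: int) -> float:
        return math.hypot(self._x[j] - self._x[i], self._y[j] - self._y[i])

    def _choose_target(self) -> int:
        females = list(range(1, 1 + self.arena.n_females))
        if self._last_target == -1:
            return int(self.rng.choice(females))
        if len(females) == 1:
            return females[0]
        if self.rng.uniform() < self.behavior.p_switch:
            others = [f for f in females if f != self._last_target]
            return int(self.rng.choice(others))
        return self._last_target

    def _disengage(self) -> None:
        # aborting males reorient away from the female before roaming off
        if self._target != -1:
            self._heading[0] = (self._bearing_to(0, self._target) + 180.0
                                + self.rng.uniform(-45, 45)) % 360.0
        self._state = _ROAM
        self._target = -1
        self._pause_frames = self._draw_frames(self.behavior.mean_pause_s)

    # -- per-frame update --------------------------------------------------

    def step(self, stim_active: bool = False) -> None:
        """Advance one frame; ``stim_active`` marks an LED-on frame."""
        rng = self.rng
        dt = self.dt

        # females: slow random walk with heading diffusion, veering away from
        # any fly they are about to collide with
        sigma_f = _FEMALE_TURN_DEG_SQRT_S * math.sqrt(dt)
        for i in range(1, 1 + self.arena.n_females):
            self._heading[i] += rng.normal(0.0, sigma_f)
            near, near_d = -1, _COLLISION_AVOID_MM
            for j in range(1 + self.arena.n_females):
                if j != i and self._dist(i, j) < near_d:
                    near, near_d = j, self._dist(i, j)
            if near >= 0:
                self._heading[i] = (math.degrees(
                    math.atan2(self._y[i] - self._y[near],
                               self._x[i] - self._x[near]))
                    + rng.uniform(-30, 30))
            th = math.radians(self._heading[i])
            self._x[i] += _FEMALE_SPEED_MMS * dt * math.cos(th)
            self._y[i] += _FEMALE_SPEED_MMS * dt * math.sin(th)
            if self._clamp_to_wall(i):
                # turn back toward the centre after hitting the sloped wall
                self._heading[i] = (math.degrees(math.atan2(-self._y[i], -self._x[i]))
                                    + rng.uniform(-45, 45))
            self._heading[i] %= 360.0

        # stimulus onset: the male may abort his pursuit (once per episode)
        if stim_active and not self._prev_stim:
            if (self._state in (_APPROACH, _COURT)
                    and rng.uniform() < self.behavior.p_abort_on_stimulus):
                self._disengage()
        self._prev_stim = stim_active

        # male state machine
        if self._state == _ROAM:
            if self._pause_frames > 0:
                self._pause_frames -= 1
            elif rng.uniform() < self._p_init_frame:
                self._target = self._choose_target()
                self._last_target = self._target
                self._state = _APPROACH

        if self._state == _ROAM:
            self._heading[0] += rng.normal(0.0, _ROAM_TURN_DEG_SQRT_S * math.sqrt(dt))
            near, near_d = -1, _ROAM_AVOID_DIST_MM
            for i in range(1, 1 + self.arena.n_females):
                if self._dist(0, i) < near_d:
                    near, near_d = i, self._dist(0, i)
            if near >= 0:
                away = math.degrees(math.atan2(self._y[0] - self._y[near],
                                               self._x[0] - self._x[near]))
                self._heading[0] = away + rng.uniform(-30, 30)
            th = math.radians(self._heading[0])
            self._x[0] += self.behavior.speed_roaming_mms * dt * math.cos(th)
            self._y[0] += self.behavior.speed_roaming_mms * dt * math.sin(th)
            if self._clamp_to_wall(0):
                self._heading[0] = (math.degrees(math.atan2(-self._y[0], -self._x[0]))
                                    + rng.uniform(-60, 60))
            # a disengaged male steers around females so that incidental
            # passes (including wall turns beside a female) never satisfy
            # the courtship geometry; pursuit happens only through the
            # courtship states, keeping intent and predicate aligned
            if near >= 0:
                away = math.degrees(math.atan2(self._y[0] - self._y[near],
                                               self._x[0] - self._x[near]))
                self._heading[0] = away + rng.uniform(-30, 30)
        else:
            t = self._target
            dist = self._dist(0, t)
            bearing = self._bearing_to(0, t)
            if self._state == _APPROACH:
                # detour around the other female if she is in the way, so the
                # approach never satisfies the predicate toward a non-target
                self._heading[0] = bearing
                for i in range(1, 1 + self.arena.n_females):
                    if i == t or self._dist(0, i) >= _ROAM_AVOID_DIST_MM:
                        continue
                    b_other = self._bearing_to(0, i)
                    off = (b_other - bearing + 180.0) % 360.0 - 180.0
                    if abs(off) < 45.0:
                        # sidestep: head perpendicular to her, on the side
                        # where the target lies
                        side = -1.0 if off > 0 else 1.0
                        self._heading[0] = b_other + side * 90.0
                        break
                bearing = self._heading[0]
                step_len = min(self.behavior.speed_courting_mms * dt,
                               max(dist - _FOLLOW_DIST_MM, 0.0))
                th = math.radians(bearing)
                self._x[0] += step_len * math.cos(th)
                self._y[0] += step_len * math.sin(th)
                if self._dist(0, t) < _COURT_ENTRY_DIST_MM:
                    self._state = _COURT
                    self._bout_frames = self._draw_frames(self.behavior.mean_bout_s)
                    self._bout_t0 = self.frame * dt
                    self._wing_side = int(rng.uniform() < 0.5)
            else:  # _COURT: hold station just behind the female, facing her
                self._heading[0] = bearing + rng.normal(0.0, _COURT_HEADING_JITTER_DEG)
                if dist > _FOLLOW_DIST_MM:
                    step_len = min(self.behavior.speed_courting_mms * dt,
                                   dist - _FOLLOW_DIST_MM)
                    th = math.radians(bearing)
                    self._x[0] += step_len * math.cos(th)
                    self._y[0] += step_len * math.sin(th)
                self._bout_frames -= 1
                if self._bout_frames <= 0:
                    self._disengage()
            self._clamp_to_wall(0)
        self._heading[0] %= 360.0

        # record
        courting = self._target if self._state == _COURT else -1
        self._labels.append(courting)
        wl = wr = 0.0
        if courting != -1:
            phase = 2 * math.pi * _WING_FREQ_HZ * (self.frame * dt - self._bout_t0)
            ext = _WING_MAX_DEG * abs(math.sin(phase))
            wl, wr = (ext, 0.0) if self._wing_side == 0 else (0.0, ext)
        for i in range(1 + self.arena.n_females):
            self._rows.append((self.frame, i, self._x[i], self._y[i],
                               self._heading[i],
                               wl if i == 0 else 0.0, wr if i == 0 else 0.0,
                               "male" if i == 0 else "female"))
        self.frame += 1

    def run(self, n_frames: int | None = None) -> None:
        if n_frames is None:
            n_frames = self.arena.n_frames
        for _ in range(n_frames):
            self.step()

    # -- outputs -----------------------------------------------------------

    def trajectory_table(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=TRAJECTORY_COLUMNS)

    def current_frame_table(self) -> pd.DataFrame:
        """Trajectory rows of the most recently stepped frame."""
        n = 1 + self.arena.n_females
        return pd.DataFrame(self._rows[-n:], columns=TRAJECTORY_COLUMNS)

    def bout_table(self) -> pd.DataFrame:
        """Ground-truth courtship bouts as half-open frame intervals."""
        rows = []
        labels = self._labels
        fps = self.arena.fps
        start = None
        cur = -1
        for f, lab in enumerate(labels):
            if lab != cur:
                if cur != -1:
                    rows.append((start, f, cur, (f - start) / fps))
                start, cur = f, lab
        if cur != -1:
            rows.append((start, len(labels), cur, (len(labels) - start) / fps))
        return pd.DataFrame(rows, columns=BOUT_COLUMNS).astype(
            {"start_frame": int, "end_frame": int, "target_id": int})


def simulate_session(arena: ArenaConfig, behavior: BehaviorParams):
    """Run a full session; returns ``(trajectory_table, bout_table)``.

    Identical inputs (including ``behavior.seed``) give identical outputs.
    A zero-duration session yields empty tables.
    """
    sim = ArenaSimulator(arena, behavior)
    sim.run()
    return sim.trajectory_table(), sim.bout_table()


# ---------------------------------------------------------------------------
# Detection rendering
# ---------------------------------------------------------------------------

def render_detections(truth: pd.DataFrame, noise: NoiseParams,
                      fps: float = 30.0,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Corrupt a ground-truth trajectory into a per-frame detection stream.

    Each surviving fly emits one detection with jittered head/thorax/abdomen
    keypoints, a uniform confidence in ``[conf_low, conf_high]`` and a sex
    label that is wrong with probability ``sexlabel_error``.  Flies are
    dropped per frame with probability ``dropout_base`` plus
    ``dropout_speed_gain`` per mm/s of speed; two flies whose centroids are
    closer than ``occlusion_dist_mm`` merge into a single low-confidence
    detection at their midpoint.  ``truth_id`` / ``truth_merged_with``
    columns retain the generating identity for evaluation only.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    if len(truth) == 0:
        return pd.DataFrame(columns=DETECTION_COLUMNS)

    df = truth.sort_values(["fly_id", "frame"], kind="mergesort")
    frames = df["frame"].to_numpy()
    flies = df["fly_id"].to_numpy()
    x = df["x_mm"].to_numpy(float)
    y = df["y_mm"].to_numpy(float)
    heading = df["heading_deg"].to_numpy(float)
    sex = df["sex"].to_numpy()
    # per-fly speed in mm/s from consecutive rows of the same fly
    speed = np.zeros(len(df))
    same = np.empty(len(df), dtype=bool)
    same[0] = False
    same[1:] = (flies[1:] == flies[:-1]) & (frames[1:] == frames[:-1] + 1)
    dstep = np.hypot(np.diff(x), np.diff(y))
    speed[1:][same[1:]] = dstep[same[1:]] * fps

    drop_p = np.clip(noise.dropout_base + noise.dropout_speed_gain * speed, 0, 1)
    keep = rng.uniform(size=len(df)) >= drop_p

    # order kept rows by frame for the merge pass
    order = np.lexsort((flies[keep], frames[keep]))
    kf = frames[keep][order]
    kid = flies[keep][order]
    kx = x[keep][order]
    ky = y[keep][order]
    kh = heading[keep][order]
    ksex = sex[keep][order]
    klen = np.where(ksex == "male", MALE_BODY_LENGTH_MM, FEMALE_BODY_LENGTH_MM)

    kps = pose_to_keypoints(kx, ky, kh, klen)  # (n, 3, 2)

    # occlusion merging, frame by frame over the kept detections
    out_kp: list[np.ndarray] = []
    out_id: list[int] = []
    out_other: list[int] = []
    out_sex: list[str] = []
    out_frame: list[int] = []
    out_merged: list[bool] = []
    bounds = np.flatnonzero(np.diff(kf)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [len(kf)]))
    occl = noise.occlusion_dist_mm
    for s, e in zip(starts, ends):
        idx = list(range(s, e))
        merged_away: set[int] = set()
        if occl > 0 and e - s >= 2:
            pairs = []
            for a in range(s, e):
                for b in range(a + 1, e):
                    d = math.hypot(kx[a] - kx[b], ky[a] - ky[b])
                    if d < occl:
                        pairs.append((d, a, b))
            pairs.sort()
            for d, a, b in pairs:
                if a in merged_away or b in merged_away:
                    continue
                merged_away.add(b)
                pick_a = rng.uniform() < 0.5
                keep_i, other_i = (a, b) if pick_a else (b, a)
                out_kp.append((kps[a] + kps[b]) / 2.0)
                out_id.append(int(kid[keep_i]))
                out_other.append(int(kid[other_i]))
                out_sex.append(str(ksex[keep_i]))
                out_frame.append(int(kf[a]))
                out_merged.append(True)
                merged_away.add(a)
        for i in idx:
            if i in merged_away:
                continue
            out_kp.append(kps[i])
            out_id.append(int(kid[i]))
            out_other.append(-1)
            out_sex.append(str(ksex[i]))
            out_frame.append(int(kf[i]))
            out_merged.append(False)

    n = len(out_frame)
    if n == 0:
        return pd.DataFrame(columns=DETECTION_COLUMNS)
    kp = np.stack(out_kp)  # (n, 3, 2)
    if noise.keypoint_jitter_mm > 0:
        kp = kp + rng.normal(0.0, noise.keypoint_jitter_mm, size=kp.shape)
    conf = rng.uniform(noise.conf_low, noise.conf_high, size=n)
    conf = np.where(out_merged, noise.conf_low, conf)
    labels = np.array(out_sex, dtype=object)
    flip = rng.uniform(size=n) < noise.sexlabel_error
    labels[flip] = np.where(labels[flip] == "male", "female", "male")

    xmin = kp[:, :, 0].min(axis=1) - _BOX_PAD_MM
    xmax = kp[:, :, 0].max(axis=1) + _BOX_PAD_MM
    ymin = kp[:, :, 1].min(axis=1) - _BOX_PAD_MM
    ymax = kp[:, :, 1].max(axis=1) + _BOX_PAD_MM

    out = pd.DataFrame({
        "frame": np.array(out_frame, dtype=int),
        "box_xmin": xmin, "box_ymin": ymin, "box_xmax": xmax, "box_ymax": ymax,
        "head_x": kp[:, 0, 0], "head_y": kp[:, 0, 1],
        "thorax_x": kp[:, 1, 0], "thorax_y": kp[:, 1, 1],
        "abdomen_x": kp[:, 2, 0], "abdomen_y": kp[:, 2, 1],
        "confidence": conf,
        "sex_label": labels,
        "truth_id": np.array(out_id, dtype=int),
        "truth_merged_with": np.array(out_other, dtype=int),
    })
    out = out.sort_values(["frame", "truth_id"], kind="mergesort",
                          ignore_index=True)
    return out[DETECTION_COLUMNS]
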