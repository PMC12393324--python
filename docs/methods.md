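# Methods

## The pipeline and its assumptions

`courtrack` models the computational chain of a closed-loop fly courtship
experiment: per-frame pose detections are associated into persistent
identities, identities are protected against male/female swaps, behavior is
scored geometrically, and a proximity/orientation trigger drives optogenetic
episodes that feed back on the animal's behavior. The design assumption
throughout is a fixed, known cast — one male plus one or two females in a
38 mm circular arena sampled at 30 Hz — with courtship defined purely by
pose: the male within 5 mm of a female, holding her inside a 60° frontal
cone (interpreted as facing angle ≤ 30°, the full-cone-width convention;
configurable). Close-range encounters use the same cone with a 2 mm radius,
and the closed-loop trigger is exactly that encounter rule applied to a
designated female.

Distances are measured thorax-to-thorax (centroid); coordinates are in
millimetres, origin at the arena centre, y up; headings in degrees CCW from
+x in [0, 360); frames are 0-based and all intervals half-open.

## Tracking

The association cost between a tracklet and a detection is the keypoint
distance: the mean Euclidean distance over corresponding head/thorax/abdomen
keypoints. Relative to box overlap this folds orientation into the cost, so
two nearly coincident flies facing different ways remain separable. Matching
runs in two stages per frame, each solving the optimal one-to-one assignment
on the KD cost matrix and pruning matched pairs above the stage's distance
gate afterwards (solve-then-prune; when the gate exceeds all matched costs
this coincides with gate-aware solving, which the test suite asserts):

* stage 1 — detections with confidence > 0.1, active tracks, gate
  `dist_stage1_mm` (default 2.0 mm, the plausible per-frame displacement of
  a walking fly at 30 Hz);
* stage 2 — remaining detections with confidence > 0.3, unmatched active
  *and lost* tracks, gate `dist_stage2_mm` (default 6.0 mm) to relink after
  sprints and brief occlusions.

Unmatched tracks become lost and retire after `max_lost_frames` (default 30,
one second). New tracks are seeded from stage-1-eligible unmatched
detections only while the live-track count is below the configured fly
count; with a known cast this suppresses duplicate identities. No motion
model is used: the cost is computed against the track's last observed
keypoints.

The identity guard operates downstream on detector sex labels. Each track
accumulates exponentially decaying sex votes (half-life 300 frames, so stale
labels cannot outvote recent ones). A male-labeled frame on a non-canonical
track increments a divergence counter (reset when the label returns,
*unchanged* when no unambiguous male label exists — absence of the male is
not evidence of a swap); at `n_consecutive` = 15 divergent frames (0.5 s)
the two tracks' identities and vote histories are exchanged and the event
logged. Independently, every 120 frames the male identity is re-derived
from the vote tallies, bounding the lifetime of any drift at
`n_consecutive + 120` frames. In two-female sessions only the male identity
is protected; the females are interchangeable for the guard.

## The simulator

The generator exists so that every downstream stage can be scored against a
known truth. The male follows a two-state semi-Markov model: *roaming*
(random walk at `speed_roaming_mms`, default 5 mm/s) and *courting* a chosen
female (close pursuit at up to `speed_courting_mms`, default 10 mm/s,
holding ~1.8 mm behind her with ~4° of heading noise). Dwell times are
exponential (`mean_bout_s` = 20 s, `mean_pause_s` = 5 s); after the pause
the male initiates with per-second probability `p_initiate` = 0.5 and
switches target with probability `p_switch` = 0.8 per initiation, matching
the high switching propensity seen after courtship interruptions. An active
stimulus episode aborts pursuit with probability `p_abort_on_stimulus`
(evaluated once per episode, at its onset); `1.0` represents a reliably
responding experimental male and `0.0` the no-effect control. Females walk
slowly (4 mm/s) with diffusing headings — a stand-in, not an inference about
real female kinematics.

Three behavioral details keep the hidden intent aligned with the geometric
predicate, so that ground-truth labels and pose-derived scores can be
compared at all: bouts are labeled from the frame the predicate first holds
(the approach leg points at the female, so this is the 5 mm crossing);
aborting males reorient *away* from the female before roaming off, as
interrupted males do; and flies steer around each other outside of pursuit
(a roaming male avoids females within 6 mm, an approaching male detours
around the non-target, females veer off any fly within 2.2 mm). Without
these, wall turns and incidental passes generate one-frame predicate blips
that a scorer must count as courtship although the generator never intended
any. Wing angles trace 0–45° sinusoidal extensions on one wing during bouts
(for the wing-song mask; song is visualization, not a courtship criterion).

The detection renderer then applies the documented failure modes of a
real-time pose detector: isotropic keypoint jitter (default 0.1 mm),
per-frame dropouts with a speed-dependent term (base 0.02 plus 0.002 per
mm/s — fast flies go undetected), sex-label errors (default 5%), uniform
confidence scores in [0.2, 1], and occlusion merging: two flies with
centroids closer than 1.5 mm (bodies are 2.0/2.5 mm, so boxes overlap
heavily below that) emit a single detection at their keypoint midpoints with
the floor confidence. True identities ride along in `truth_*` columns used
only for evaluation.

What passing tests show — and what they do not: the synthetic streams
exercise geometry, association logic, identity bookkeeping, and the
trigger/behavior feedback loop under controlled noise. They do not emulate
detector appearance failures (systematic keypoint biases, correlated
errors, lighting), copulation, grooming, or real female responses to
courtship, so quantitative accuracies measured here do not transfer to real
video.

## Closed loop

`run_closed_loop` advances the simulator frame by frame; when the trigger
rule holds and the refractory gap (default 500 ms — one pulse cannot
retrigger mid-pulse; the alternative of immediate retriggering under
sustained proximity is not modeled) has elapsed, a 500 ms episode is
scheduled from the next frame, mirroring an acquisition → compute → deliver
cycle. Episodes are never truncated: a trigger too close to the session end
is ignored so every logged episode is exactly `round(pulse_ms·fps/1000)`
frames. The preference readout uses the control (non-designated) female as
side A, so positive PI means preference for the female that triggered no
stimulation.

By default the trigger reads ground-truth poses. The online tracker+guard
can be placed in the loop (`use_tracking=True`), in which case the male pose
comes from his track's head–thorax axis and the designated female is the
track nearest her position when all flies first have live tracks — the
software analogue of the experimenter designating a female at assay start. A
test asserts that on noiseless sessions both paths produce identical
stimulus logs; the ground-truth default keeps multi-hundred-seed sweeps
cheap while remaining behaviorally equivalent under those conditions.

## Numerical and interface choices

* Assignment uses `scipy.optimize.linear_sum_assignment`; ties between
  equal-cost optima resolve deterministically for a given matrix, and all
  stochastic components run on seeded `numpy` generators, so every pipeline
  output is reproducible bit for bit from its seed.
* `facing_angle` returns NaN for coincident positions and propagates it.
* The wing-song threshold (default 30°) is closed at the threshold
  (≥ counts as song).
* Stimulus-evoked pauses are censored at the analysis window (default 30 s)
  when courtship never resumes.
* The quality-by-depth site filter is applied as an *upper* bound
  (QD < 1.5) as specified, although conventional hard filtering bounds QD
  from below; `qd_upper_bound=False` flips the comparator.
* π is reported both site-pooled (Σ variants / Σ sites) and as the
  unweighted per-transcript mean, since either pooling convention is
  defensible; the call-rate screen (95%) applies across every strain column
  present in the table, and the coverage screen (15x) per pair.
* ΔF/F₀ uses the first 20 samples of the pre-stimulus window as baseline by
  default, with a configurable offset.

## Evaluation metrics

Tracker output is scored against the simulator's identity side channel.
Each detection-backed track row is attributed to the nearest truth fly
(within 3 mm); per truth fly, a change of attributed track id counts as an
*identity switch* when the new track had been following a different fly and
a *fragmentation* otherwise. Male-identity accuracy is the fraction of
frames on which the guard's male track lies within 2.5 mm (about one body
length) of the true male position — during a merged-detection occlusion the
shared track sits between the two flies and still qualifies, which is the
correct reading since the assignment is genuinely ambiguous there.

## Problem sizes

The seeded sweeps behind the test suite and `scripts/acceptance.py` use:
one 600 s noiseless three-fly session (18,000 frames) for perfect-input
tracking; 50 seeds of 300 s sessions for the noisy identity-guard and
ethogram-recovery medians; 100 seeds each of 300 s closed-loop assays for
the experimental (`p_abort = 1`) and control (`p_abort = 0`) preference
distributions, plus 50 at `p_abort = 0.5` for the dose-response ordering;
500 random cost matrices (up to 6×6) against the exhaustive-permutation
oracle and 1,000 random keypoint pairs against the per-keypoint loop.

## Known limitations

* The simulator's courting male holds a fixed follow distance; real pursuit
  has richer kinematics (circling, tapping lunges, copulation attempts).
* Merged occlusion detections average the two poses; a real detector more
  often reports the occluding fly. Consequently post-occlusion separation
  is symmetric here and resolved by the sex-label guard rather than by
  appearance.
* Copulation is an injected timestamp, not a simulated event.
* The tracker carries no motion model; at frame rates far below 30 Hz the
  stage gates would need retuning.
* Switch statistics are reported for any male with at least one bout;
  whether non-courters should be excluded is left to the caller.
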