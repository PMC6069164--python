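# Methods

This note documents the models and procedures implemented in
`fallsense`, the assumptions behind them, the tunable parameters, and
what the synthetic-data tests do and do not demonstrate.

## Input model

A skeleton stream is a sequence of time-stamped frames, each holding up
to 20 named joints (head, shoulder centre, torso/spine, hip centre, and
left/right shoulders, elbows, wrists, hands, hips, knees, ankles, feet)
in metric sensor space — x to the subject's right, y up, z away from
the sensor — plus the floor-clipping plane `(A, B, C, D)` the depth
sensor reports, where `D` is the camera height above the floor in
meters (default placement ≈ 0.91 m, i.e. about three feet).  Frames
arrive nominally at 30 Hz; spacing is validated against the declared
fps with 20 % tolerance and out-of-tolerance gaps are flagged before
kinematics are trusted.  Joints carry a tracking state; every derived
quantity treats `not_tracked` joints as unavailable rather than
numeric, and operations that need them signal unavailability instead of
raising mid-pipeline.

Skeleton tracking itself is out of scope: the package consumes joints
an SDK has already fitted, from CSV or JSON-lines files (one record per
frame, `<joint>_{x,y,z,state}` fields) or from the simulator.

### Accelerometer adapter

Some public fall benchmarks ship only an accelerometer-magnitude trace
plus depth images.  For those, `height_series_from_acceleration`
reconstructs a head-height trace from an initial height by subtracting
the variation of the signal around gravity.  Two selectable heuristics
are provided: literal cumulative subtraction of `|a − g|·Δt·scale`
(default — the height only decreases while the signal is perturbed),
and double integration of `a − g` treated as a vertical acceleration.
Both are benchmark-emulation devices, not physical models: an
acceleration magnitude does not determine a trajectory.  Units must be
declared explicitly (`m/s2` or `g`) because such exports rarely declare
them.

## Kinematics

- **Height** is the point-to-plane distance
  `|Ax + By + Cz + D| / sqrt(A² + B² + C²)`.  The normalization term
  makes the result invariant to rescaling the plane vector, which
  sensors do not guarantee to be unit length.
- **Skip-one sampling**: positions are compared two frames apart
  (`frame_skip = 1`), the 1/15 s interval at 30 fps.  This doubles the
  displacement-to-jitter ratio relative to adjacent frames at
  negligible latency cost.
- **Direction** of the tracking joint (default shoulder centre) is
  classified as stationary below `stationary_epsilon = 0.01` m per
  sample, as axis-aligned when one axis carries at least
  `dominance_ratio = 0.8` of the Euclidean displacement (ties go to the
  axis), and as irregular otherwise.  Irregular displacement uses the
  2-D in-plane Euclidean length `hypot(Δx, Δy)`; a config flag
  generalizes it to 3-D but is off by default.
- **Speed** per channel is `|Δ| / Δt`.  The detector branches on the
  maximum of the tracking-joint displacement speed and the key-joint
  (head, shoulder centre, hip centre) height speeds.
- **Acceleration** has no canonical definition for skeleton data; it is
  taken as the first difference of the 3-sample-median-smoothed speed
  over the frame interval.  Unsmoothed double differencing at 30 fps
  would amplify centimetre jitter into tens of m/s².

## Fall-risk factors

The three gait factors are computed on pairs of frames (PF, CF):

- **step symmetry** — difference between the foot separations
  `R_foot − L_foot` of PF and CF, measured along the movement axis
  (x-coordinates when walking along x, z-coordinates when walking along
  z).  By default the separation *magnitudes* are differenced.  With PF
  and CF one step apart, `|R − L|` is alternately the right and the
  left step length, so the factor estimates the left/right step
  inequality directly; the signed variant (`rectify_step: false`) is
  retained but is provably blind to systematic step-length inequality
  for periodic gait, since differencing a periodic signal at any fixed
  lag cancels both its mean and its period-commensurate components.
- **trunk sway** — the lateral (axis orthogonal to movement) offset of
  the torso from the hip midpoint, averaged over the two frames.
  Averaging at a half-stride lag cancels stride-periodic sway and
  passes quasi-static lean, so the factor reads sustained lateral lean.
- **arm spread** — change in the mean lateral torso-to-hand distance
  from PF to CF; positive when the arms open, as in a
  balance-recovery reaction.  "Arm" resolves to the distal hand joint
  via a configurable alias table (`torso` resolves to the spine joint).

The PF/CF lag is one step period, estimated per window as half the lag
of the strongest foot-separation autocorrelation peak within a
0.8–2.5 s stride-period search range (minimum normalized correlation
0.2); aperiodic windows (standing, sitting) fall back to
`pair_lag_frames = 10`.  Coordinate series feeding the factors are
rolling-median smoothed over 5 frames.

A window of `window_frames = 60` factor samples (2 s) is aggregated by
the mean of absolute values (`max_abs` available), and the risk level is
**high** as soon as any aggregate exceeds its threshold — an OR rule,
since any single abnormality warrants intensive monitoring.  Defaults:
step symmetry 0.10 m, trunk sway 0.05 m, arm spread 0.15 m.  No
canonical thresholds exist for these quantities; the defaults sit
roughly halfway between what the simulator's normal and impaired gait
presets produce (normal ≈ 0.03 / 0.005 / 0.005 m, weak ≈ 0.16 / 0.10 /
0.12 m), and all are config-exposed.  Windows with too few samples
raise an insufficient-data signal; the detector then falls back to the
low-risk path and logs the caveat.

## Detection algorithm

Five processes in two stages; all thresholds live in the
`detector.*` config namespace.

**Stage 1 — candidates.**
- *P1 subject detection*: head, shoulder centre and hip centre must be
  tracked.
- *P2 initial assessment*: computes speed, heights and the rolling risk
  flag over the shared buffer; speed > `velocity_high = 2.0 m/s` raises
  an immediate candidate (2 m/s and the 0.5 m near-floor threshold
  below are the values depth-sensor fall-detection practice converged
  on).  Otherwise the branch is chosen: high risk → P3, else → P4.
- *P3 risk-adapted detection*: speed recomputed at every frame (no
  skip) against `0.75 × velocity_high`, plus a raised near-floor
  threshold `1.25 × near_floor_height`; the height rule passes through
  the same activity gate as P4 — without it, every deliberate floor
  transfer by a high-risk user would alarm, defeating the purpose of
  adaptation.
- *P4 normal detection*: head below `near_floor_height = 0.5 m` (unless
  the descent is recognized as deliberate) or acceleration above
  `acceleration_high = 10 m/s²`.

**Deliberate-descent recognizer.**  A descent is deliberate when its
monotone height-decrease run lasts at least `slow_descent_seconds = 2 s`
*and* the head's peak descent speed stays below
`slow_descent_max_speed = 1 m/s`.  Sitting or lying down takes ≈ 3.7–4 s
at ≤ 0.6 m/s peak; a fall completes in ≈ 1.3–1.9 s and contains a
collapse phase well above 1 m/s, so the two conditions separate the
cases with wide margins on both axes.  Descent runs are measured on
5-frame-median-smoothed head heights with slopes taken over a
`descent_window_frames = 10` (1/3 s) baseline — long enough to average
jitter, short enough to resolve a collapse — counting frames above
`descent_speed_threshold = 0.06 m/s` as descending, tolerating up to
`descent_grace = 8` flat frames, and terminating at any rising stretch.
Causality matters: while a descent is still in progress its peak speed
is unknowable, so the height rules then always raise the candidate and
the classification is repeated at confirmation time, when the completed
descent is visible.  Recognized deliberate descents are sticky — no new
candidate opens until the head rises above `recovery_height` — and a
rejected height-rule candidate is not re-raised until the head clears
its triggering threshold again.

**Stage 2 — confirmation (P5).**  A candidate is observed for
`confirm_window = 1.5 s` (a new speed spike during the window extends
it).  It is confirmed iff, within the window: the head goes below
`near_floor_height` and never recovers above `recovery_height = 0.8 m`;
the hip centre corroborates (median below `recovery_height` at window
end); the height trace shows a net drop of at least
`fluctuation_amp = 0.15 m` from the pre-candidate maximum (looking back
`descent_lookback = 2 s`) — walking and running height fluctuations
stay below this amplitude, so speed spikes from gait are rejected; and
the completed descent is not deliberate per the recognizer above.
Rejections carry the discriminating evidence.  One candidate is open at
a time; a confirmed fall suppresses further candidates until the
subject rises.  Candidates unresolved at stream end are reported as
such.  The detector is fully deterministic: identical stream and config
give byte-identical serialized event logs.

## Synthetic motion generator

The simulator renders activity scripts into skeleton streams by
blending posture templates (stand, sit-on-chair, sit-on-floor, lie,
crouch) with piecewise-smooth profiles, then adding per-joint Gaussian
jitter (`noise_sd = 0.01 m`, reflecting the fluctuation level of
consumer depth-sensor tracking).  Design choices that matter to the
detector:

- **Falls** (forward, from a chair, collapse while sitting down) use a
  three-phase profile — slow balance loss (35 % of the duration), rapid
  collapse (35 %), settle — because real falls are not constant-rate
  descents; a hypothetical uniform 1.9 s descent would be kinematically
  indistinguishable from deliberate lying for any height-based rule.
  Forward falls last 1.3–1.9 s, from-chair falls 1.0–1.5 s (lower start
  height), and the sit-down collapse spends ~70 % of its segment in a
  controlled partial sit before collapsing.
- **Deliberate lying** spreads its descent over 3.7–4.0 s (peak head
  speed < 1 m/s); sitting on the floor takes 3.0–3.8 s down to a 0.65 m
  head height; picking an object dips the head to ≈ 0.75 m.
- **Walking** advances at `cadence × step length` with head-height
  fluctuation ≤ 0.06 m.  Foot separation follows a plateaued wave
  (plateau ≈ 60 % of each step, mimicking stance phases) whose plateau
  equals the stepping foot's step length — which is what makes the
  step-symmetry estimator consistent with the generator's configured
  asymmetry (expected estimate ≈ 0.82 × asymmetry for these shapes).
- **Gait presets**: normal (0.35 m symmetric steps, 1.6 steps/s, 0.02 m
  oscillatory sway), slow (0.25 m, 1.2 steps/s), weak (0.25/0.45 m
  steps — 0.20 m asymmetry, 1.4 steps/s, 0.10 m quasi-static lateral
  lean, 0.25 m balance-correcting arm excursions).  Weak-gait lean is
  quasi-static because the two-frame sway average cancels
  stride-periodic components by construction.
- The **standard suite** (`standard_suite(seed)`) draws 30 fall and 40
  ADL scenarios (14 walks, 8 chair sits, 6 floor sits, 6 lie-downs, 6
  object picks) with per-scenario seeds, durations from the ranges
  above, movement along either axis, and gait styles mixed 50/25/25
  normal/slow/weak.
- An accelerometer emitter derives `|g + ḧ|` from the (heavily
  smoothed) head trajectory to exercise the adapter end-to-end.

Kinematics are stylized, not biomechanical: no ground contact model, no
limb dynamics, single subject, perfect tracking (`tracked` states
throughout), constant floor plane.  Tests passing on this generator
demonstrate that the detection logic responds correctly to the
*kinematic signatures* it keys on (drop depth, descent duration, peak
descent speed, gait asymmetry, lean); they do not demonstrate
robustness to real tracking artefacts — occlusion dropouts, joint
swaps, floor-plane drift — or to the diversity of real human motion.

## Evaluation

Scoring is sequence-level, matching how such benchmarks count whole
events: a sequence is detected-positive iff it contains at least one
confirmed fall; falls are the positive class.  Metrics are accuracy,
sensitivity, specificity and precision in percent, rounded to two
decimals; a metric with an empty denominator is reported as unavailable
rather than zero.  `scripts/acceptance.py` reports both the metric
quadruple for the published benchmark confusion counts (29/1/33/7) and
the end-to-end quadruple on the seeded standard suite.  Problem sizes
were chosen to keep the whole test suite under a minute of simulation:
70 suite sequences of 6–12 s and 100 + 100 eight-second walks for the
risk-recovery checks.

## Numerical and degenerate-input policy

- Degenerate floor planes (zero normal) and non-increasing timestamps
  are rejected at construction; camera height must be non-negative.
- Untracked joints propagate as unavailable values (`None`/NaN), never
  as zeros; streams whose key joints are untracked produce no events
  plus a logged notice.
- Axis-dominance ties classify as axis-aligned (≥, not >); the
  stationarity epsilon is applied to the total displacement.
- File round-trips are guaranteed to 6 decimal places (micrometre
  precision, far below sensor noise).
- All randomness flows through `numpy.random.default_rng(seed)`; the
  suite derives per-scenario child seeds below 2³¹.

## Known limitations

- Single-subject streams only; no multi-person tracking or identity.
- No alarm delivery, no real-time capture loop; streams are replayed
  from files or generated.
- The height-from-acceleration adapter is a coarse heuristic and is
  expected to degrade detection relative to true skeleton input.
- Risk thresholds are calibration choices validated against the
  simulator's presets, not clinical gait norms; deployments should
  re-calibrate per sensor and population.
- The confirmation logic assumes the subject stays in view; a fall
  ending outside the frustum leaves an unresolved candidate rather
  than a confirmed fall.
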