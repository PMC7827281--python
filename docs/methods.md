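# Methods

`gerofit` re-implements the computational core of a depth-sensor exercise
system for older adults: the skeletal geometry, the biometric calibration,
the rule-based validity assessment with elderly-adapted tolerance margins,
the per-repetition range-of-motion (ROM) measurement, the swipe-gesture
recognizer, and the nonparametric session-progress analytics. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic-data generator does and does not emulate.

## Skeletal model and coordinate convention

Input is a stream of timestamped frames, each holding the 3D camera-space
positions of the standard 25-joint skeleton produced by consumer
depth-sensing SDKs (SPINE_BASE … THUMB_RIGHT). The sensor's depth working
range is 0.4–4.5 m; a frame with any joint outside that range is *flagged*,
not dropped, and assessment refuses a stream with more than 10 % flagged
frames (fail loudly on bad capture rather than silently interpolate).

The sensor convention is not uniquely determined by the joint set, so the
package fixes one and documents it: right-handed, meters, origin at the
sensor, **+y up**, **+z from the sensor toward the user**, +x completing
the triad, user facing the sensor. Only two computations depend on it:
torso tilt (vertical = +y) and the knee-over-toe check (anteroposterior =
z, forward = decreasing z).

All angle primitives are interior angles from the arc-cosine of the
normalized dot product, clipped to [−1, 1], reported in degrees in
[0, 180]. Zero-length segments raise a degenerate-pose error rather than
returning NaN.

## Calibration

Calibration captures ≥ 1 s of the user standing relaxed. Resting joint
positions are per-joint coordinate-wise means; the mean is anchored at the
first frame (`x₀ + mean(x − x₀)`) so that a perfectly static capture is
recovered *exactly*, making calibration idempotent. Stationarity is
enforced as a per-joint resultant positional standard deviation ≤ 2 cm —
generous for elderly postural sway, tight enough to reject a user
mid-movement (a 12 cm hand drift is rejected; 2 mm tracking jitter is not).

From the resting pose the user-specific limb vectors are derived: arm
S→E, forearm E→W, thigh H→K, shank K→A; the upper-limb length is
|SE| + |EW|. The goal coordinate of an angular exercise is the endpoint of
the straight upper limb rotated by the target angle from the downward
direction within the frontal plane (camera x–y), anchored at the resting
shoulder — so it always lies on the sphere of radius `upper_limb_length`
about the shoulder. The full limb length is used (the alternative —
upper-arm only — would place the goal at the elbow's reach; the extended
limb endpoint is the geometrically natural reading of "raise the arm to
the target"). Goal coordinates and all achievement angles are *reported*
at 5 decimal places; internally full double precision is kept, since
rounding coordinates before geometry would corrupt invariants at the 1e−5
level.

## Exercise catalog and tolerance margins

Two tolerance profiles ship:

| parameter | elderly | strict (young adult) |
|---|---|---|
| torso tilt limit | 20° | 5° |
| knee deviation limit | 10 cm | 0 cm |
| angular goal tolerance | 5° | 2° |
| retraction k | 10 frames | 10 frames |
| retraction ε | 0.03 m | 0.03 m |

The torso-tilt and knee-deviation limits are the system's printed margins;
the angular goal tolerance is a documented default (the margins are
described as relaxed and customized, without a printed number). k ≈ 0.33 s
at 30 Hz and ε = 3 cm are documented defaults chosen so the retraction
rules are demanding but achievable; both are configurable per user — small
k makes the deformation conditions more local and demanding.

The shipped catalog holds 52 exercises: 29 shoulder (flexion, abduction,
rotation × side × target, plus five isometric scapular-retraction holds)
and 23 knee (double-leg squats, extension, retraction, protraction ×
side × target). The individual entries are systematically generated
template instances — the movement families and counts are faithful; the
individual prescriptions are placeholders a physiotherapist would
overwrite via `--catalog`.

## Assessment

**Repetition segmentation** (no published rule exists) uses hysteresis on
the controlled angle relative to its calibrated resting value: a
repetition opens when the excursion exceeds 10° and closes when it returns
below 5°. The two thresholds make segmentation robust to tracking jitter
(a few mm of jitter moves the angle well under 5°) and prevent
double-counting at the boundary. A repetition still open at the end of the
stream is closed at the final frame, which keeps every reported quantity
causal: truncating a stream never changes violations already reported.

**Concentric exercises** (e.g. shoulder abduction): the controlled angle
is the arm-vs-body elevation — shoulder→wrist against the downward torso
axis — so a compensatory torso lean does not inflate the reading. The
measured ROM is the maximum excursion in the repetition, recorded to
5 decimals (ties rounded away from zero). Validity requires torso tilt
within the profile limit at *every* frame of the repetition; the first
offending frame is named. The goal is met when the measured angle reaches
the target minus the angular tolerance (one-sided, in the direction of
difficulty), and only if the repetition is valid.

**Double-leg squat**: the controlled angle is the knee flexion
(hip–knee–ankle), 180° upright to 90° with thighs parallel to the floor;
lower is better. The measured ROM is the *worse* (larger) of the two
knees' minima — a bilateral exercise is only as deep as its shallower
side. Validity requires each knee's anteroposterior advance beyond its
foot joint, `max(0, z_foot − z_knee)`, to stay within the deviation limit
at every frame. The foot joint proxies the tip of the feet; the check
assumes the user faces the sensor.

**Isometric scapular retraction**: with R, S, L the right shoulder, upper
spine and left shoulder, at every frame t ≥ k four conditions are checked
against frame t−k: |RS| and |LS| non-decreasing, |RL| non-increasing, and
|RS| − |LS| symmetric within ε. The hold duration is the longest
contiguous span where all four hold ((m−1)/rate for m frames); the trace
records which condition — and which shoulder — failed, so feedback can
name the side to correct. The goal is met when the hold reaches the
target.

**Numerical slack**: every comparison against a tolerance limit carries a
1e−9 absolute slack, so a pose exactly *at* a printed margin (20° tilt,
10 cm advance) classifies as valid instead of flipping on arccos
round-off. The slack is orders of magnitude below any physically
meaningful difference.

**Scoring**: the session performance measure is the arithmetic mean of the
per-repetition measured angles (5 decimals). The ranking score is a
documented stand-in (no published formula): 100 × the mean achievement
ratio clipped to [0, 1] — concentric `measured/target`, squat
`(180−measured)/(180−target)`, isometric `hold/target`.

## Swipe gesture

A finite-state recognizer (IDLE → ARMED → TRACKING → COMPLETED/ABORTED)
over the two hand joints. A hand arms when its height is within ±0.1 ×
user height of half the user's height (measured from the lower foot
joint) and it sits at least 5 cm lateral of its own shoulder's offset from
the spine — the margin is required because a hand hanging at rest lies
*exactly* at shoulder offset and near half height, and must not arm the
recognizer. The gesture completes at the first frame where the hand's x
crosses the SPINE_MID x toward the contralateral side; leaving the height
band first aborts the episode, and the recognizer may re-arm. The band
half-width, the clearance margin and the 2 cm tracking-travel threshold
are config defaults; no published numbers exist. Palm orientation is not
inferable from joint positions and is not checked (limitation).

## Synthetic-data generator

The simulator makes every module testable without a sensor. A body model
scales segment lengths from stature by fixed anthropometric ratios
(upper arm 0.186 h, forearm 0.146 h, thigh 0.245 h, shank 0.246 h,
biacromial half-width 0.129 h); the standing pose faces the sensor at
2.5 m. Trajectories are kinematic, not dynamic: a sin² activation profile
drives each repetition, with the frame grid chosen so the commanded
extremum lands exactly on a sampled frame — with zero noise every
kinematic statement is exact, which is what lets assessment be checked to
0.01°. Noise is independent Gaussian displacement per joint per frame
(default 5 mm, a plausible skeletal-tracking jitter); all randomness is
behind one seed.

The squat trajectory keeps ankles and feet fixed, translates the knee
toward the sensor by the commanded advance, places the hip so the interior
knee angle equals the command exactly, and translates the torso rigidly
(a "sit-back" squat with an upright trunk). The retraction trajectory
brackets the commanded static hold with a monotone ramp and release whose
lateral asymmetry exceeds ε — a symmetric monotone ramp would itself
satisfy all four conditions, leaving the hold ill-defined; the marked ramp
pins the measured hold to the commanded span within one frame period.

What the generator does **not** emulate: soft-tissue and tracking
artifacts correlated across joints and time (real sensor noise is not
i.i.d.), occlusion dropouts, anthropometric asymmetry, trembling, or
truly compensatory movement strategies. Passing tests therefore establish
the correctness of the *rules and measurements*, not robustness to every
real capture pathology.

The study generator emulates the deposited per-participant session table:
`angle = baseline(age group) + subject effect + (session−1) ×
improvement(age group) + noise`, with 57 participants (23/18/16 in age
groups 65–69/70–74/75–80; 29 men, 28 women), 6 sessions, and two
benchmark exercises. Defaults — abduction baselines 118/104/90°,
squat baselines 120/134/148°, improvement steps ±1.5/2.5/3.5°/session,
subject sd 2°, record noise sd 1° — were chosen once so the documented
qualitative pattern holds: achievement worsens with age, per-session
improvement grows with age, and the distributions are compact. Under
these conditions the within-group session 2-vs-6 contrasts are
significant below 1e−2 and the cross-age same-session contrasts below
1e−3 in essentially every seeded replicate.

## Statistics

Mann–Whitney U, Wilcoxon signed-rank and Spearman rank correlation are
computed via `scipy.stats` with the variant fixed explicitly: midranks for
ties; exact p by full enumeration when the pooled (or nonzero-difference)
sample is ≤ 12 and untied, otherwise the normal approximation with tie
correction; zeros discarded before signed ranking; all p-values
two-sided. The test suite cross-checks both tests against independent
brute-force enumeration oracles (all label assignments / all sign
assignments). Wilcoxon's W is reported as the sum of positive-difference
midranks, so antisymmetric data sits at the null center n(n+1)/4.
Boxplot summaries place whiskers at the 10th and 90th percentiles, with
values beyond them reported as outliers.

`progress_report` groups records by age range or gender and, per group ×
exercise, computes per-session summaries, both tests for each requested
session contrast (default 2–4, 4–6, 2–6), and same-session Mann–Whitney
comparisons between consecutive groups (paired Wilcoxon does not apply
across groups). Missing sessions and degenerate Wilcoxon inputs become
notes in the report, not failures.

## Problem sizes and limitations

The shipped tests and the acceptance script run on single-repetition
streams of a few seconds at 30 Hz, tolerance sweeps at integer steps, and
100 seeded study replicates — sizes chosen because the quantities being
checked (rule flip points, exact kinematic recovery, test calibration) are
already fully determined at that scale.

Known limitations: single-person streams only; the facing-the-sensor
assumption is required by the knee-over-toe axis and is not auto-detected;
goal achievement is assessed on the angle, not on the 3D distance to the
goal coordinate (the two coincide for a straight limb); the ranking score
formula is a stand-in; survey-score analytics reuse the same report
machinery but the questionnaire itself is out of scope.
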