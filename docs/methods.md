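# Methods

`orpose` quantifies intra-operative staff activity from ceiling-camera pose
detections and analyses the accompanying workload questionnaire and
hospital-schedule data. This note documents the models, the parameters that
matter, the synthetic-data generators that stand in for the (private) real
recordings, and the numerical choices made where the design was open.

## Table-activity classification

A staff member is *active at the operating table* in a frame when two
conditions hold:

1. **Zone condition.** Both wrist keypoints lie inside the annotated table
   (wrist) area, both shoulder keypoints inside the shoulder area, and the
   head centroid — the mean of whichever of nose, eyes and ears are present
   — inside the head area. Requiring the shoulder and head subsets as well
   as the wrists protects against perspective artifacts: a passer-by
   reaching an arm over the table fails the shoulder/head conditions.
   Membership is point-in-polygon with the boundary counted as inside, so
   the classifier is deterministic at zone edges. "Above the wrists" /
   "above the shoulders" is operationalized purely as membership in the
   annotated shoulder/head areas, not as a y-coordinate comparison: with a
   ceiling camera, raw image-y ordering between body parts is ill-defined.

2. **Movement veto.** The displacement of the shoulders and head between
   frame `t − 5` and frame `t` must not exceed **17.5 px**; someone moving
   faster is walking past the table, not working at it. Displacement is
   endpoint-to-endpoint over the window, not path length — "over 5 frames"
   reads most plainly as a 5-frame offset, and path length would
   double-count detector jitter. The per-point displacements (left
   shoulder, right shoulder, head centroid) are aggregated by their
   **mean** (no aggregator is canonical; the mean is robust to single-point
   jitter; `max` is available via `ActivityParams.aggregator`). The
   threshold is strict: displacement exactly equal to 17.5 px still counts
   as active. Wrist motion never enters the veto (wrists are expected to
   move during table work) and leg keypoints enter no rule at all (legs
   are unreliable under surgical aprons at these camera angles).

Frames where a required keypoint is missing, or where the displacement
window is unavailable (the first 5 frames of a track, or across gaps), are
**undetermined**, never inactive: detector dropout must not masquerade as
evidence of inactivity.

Key parameters (`ActivityParams`): `displacement_threshold` 17.5 px,
`window` 5 frames, `min_confidence` 0.3 (a keypoint below this detection
confidence counts as absent; no canonical value exists, 0.3 is a common
pose-estimator operating point and is configuration-exposed).

## Occupancy metrics and undetermined frames

Three phase-level percentages summarise a procedure (phases: patient entry
→ incision, incision → closing, closing → patient exit):

* **activity %** = 100 × combined active person-time in the phase / mean
  duration of that phase across procedures of the same surgery type. With
  several staff active at once the value exceeds 100%. The per-procedure
  denominator is available as an alternative.
* **interaction %** — the same occupancy relative to the procedure's own
  phase duration.
* **movement %** = fraction of tracked time with displacement above the
  threshold, per person, averaged across persons (a pooled person-frame
  mode exists; which of the two a practitioner prefers depends on whether
  persons or person-time is the unit of analysis).

Undetermined frames are excluded from numerator *and* denominator. This is
done by factoring each person's active fraction into (zone-pass fraction
among zone-determined frames) × (non-vetoed fraction among zone-pass frames
with a determined displacement), then scaling by the person's tracked time.
The factoring matters: an active frame needs more keypoints (zone + both
displacement endpoints) than a zone-fail frame, so under random dropout the
naive active/determined ratio is systematically low, while each factor here
is estimated on the subset whose determination does not depend on the
quantity being estimated. With no undetermined frames the estimator
reduces to a plain frame count.

Uniform coordinate rescaling leaves zone membership unchanged, but the
displacement threshold is in pixels, so rescaling is *not*
invariance-preserving for the veto; this is asserted as a negative test.

## Pose tracking

Detections are associated into tracks with a two-stage confidence split:
confident detections (mean keypoint confidence ≥ 0.5) are matched to the
active tracks first by optimal one-to-one assignment (Hungarian algorithm,
maximizing total similarity, pairs below 0.3 rejected); leftover tracks get
a second chance against low-confidence detections (≥ 0.1), which recovers
blurred or partly occluded staff instead of discarding them. Unmatched
confident detections spawn tentative tracks (confirmed after 3 hits);
tracks unseen for more than 30 frames are lost. Similarity blends
bounding-box IoU with an OKS-style keypoint term,
`0.5·IoU + 0.5·exp(−msd / 2s²)`, with `msd` the mean squared distance over
shared keypoints and `s` the mean box diagonal. No motion model is used:
OR staff move slowly relative to the frame rate, and a constant-position
model avoids velocity overshoot through occlusions. All thresholds are
configuration-exposed (`TrackerParams`); the defaults follow common
practice for confidence-split tracking, as no canonical values exist for
this setting.

## Synthetic scenes

`simulate_scene` emulates one ceiling-camera view of an OR: three nested
rectangular zones around the table (innermost for wrists), and per-person
schedules of active bouts given as (phase, start-fraction, end-fraction).
Defaults: 25 fps (configurable — real recordings vary), phase durations
60/180/60 s.

The motion model is built for sharp threshold tests rather than realism:

* During a bout a person holds a stable working stance with all required
  keypoints 11–12 px inside their zones.
* Exactly at bout boundaries they take a single **15 px step** to/from a
  "ready" stance whose required keypoints sit 3–4 px *outside* every zone.
  Because 15 ≤ 17.5, the step never triggers the veto, and the zone test
  flips exactly at the scheduled boundary — so noiseless classification
  reproduces the scheduled activity frame-exactly (outside the 5-frame
  warm-up) and recovery tests have an exact target.
* Between bouts staff idle at the ready stance; in long gaps they walk to
  a rest position at a speed whose 5-frame displacement exceeds the
  threshold by a 1.5× margin (sharp veto tests). Staff with no bouts act
  as passers-by sweeping horizontally through the table area: their zone
  test passes mid-crossing but the veto rejects them, exercising the
  passer-by rationale of the classifier.

Detections are the true keypoints plus isotropic Gaussian jitter
(`jitter_sd`) with per-keypoint dropout (`dropout_rate`), keypoint
confidences drawn from U(0.75, 0.98), and an optional per-person-frame
probability of a degraded (low-confidence) detection to exercise the
second association stage. Everything is deterministic given the seed.

What this generator does *not* model: appearance, occlusion between
people, non-rigid pose variation, camera distortion, or detector-specific
error structure (confidence correlated with error, duplicate detections).
Passing recovery tests therefore shows the pipeline implements its rules
correctly and is robust to unstructured noise — not that it would reach
the same accuracy on real recordings.

## Questionnaire model

The modified workload instrument scores seven domains — the six original
workload domains plus job satisfaction — on 0–20 scales, per surgery type
(open, minimally invasive, robotic-assisted) and per phase: up to 63 cells
per respondent. Analysis is complete-case (all 63 cells present; no
imputation). Scores are compared across types on phase-summed values
(0–60) and across phases on type-summed values, per domain, with:

* **Friedman test** — tie-corrected chi-square (Conover form), reducing to
  `12/(n k (k+1)) Σ R_j² − 3 n (k+1)` without ties, referred to χ²(k−1).
  The uncorrected statistic is reported alongside, since statistical
  packages differ in whether they correct for ties.
* **Nemenyi post-hoc** — mean-rank differences against the studentized
  range distribution, run only when the omnibus p < 0.05.
* **Effect size** — Kendall's W = χ²_F / (n(k−1)). The instrument's
  published analyses report "partial η²" without a formula for the rank
  design; W is the declared choice here (an ANOVA-style partial η² on raw
  scores is available and labelled as such), and published effect-size
  magnitudes are not treated as reproducible targets.

No multiple-testing correction is applied across the seven domains,
matching the source analysis; this is a known limitation.

The six-domain workload mean is: per respondent and type, phase-summed
scores averaged over the six original domains (satisfaction excluded),
then averaged over respondents. The aggregation behind published overall
workload means is ambiguous; this declared reading keeps the value on the
0–60 phase-sum scale, and the resulting numbers are not expected to equal
published ones.

`simulate_surgtlx` draws each cell from a normal with configured mean/SD,
**clamped** to [0, 20]. Clamping rather than resampling keeps the
generator monotone in the mean at the cost of a bias toward mid-scale for
extreme cells; recovery tests therefore compare against the closed-form
clipped-normal mean. Default cell parameters come from the published
per-type descriptive statistics for the four domains that have them
(mental, temporal, distractions, satisfaction); the remaining three
(physical, complexity, stress) use plausible mid-range values following
the same robotics-elevated pattern. Mental demand is additionally
phase-modulated to follow the published phase-level means. A
respondent-level random intercept gives any two cells of one respondent a
correlation of 0.6 (repeated-measures ratings show substantial rater-level
consistency, and within-subject tests depend on it); marginal SDs are
preserved, and per-phase SDs are `sd_type / √(3(1+2ρ))` so that the
phase-sums reproduce the published type-level SDs. One deliberate
simplification: the shared intercept makes satisfaction correlate
positively with the workload domains within a respondent, whereas in
reality they likely anti-correlate; within-domain comparisons, which are
what the tests use, are unaffected.

## Schedule metrics

Per procedure: signed deviation = actual − planned duration per phase and
in total (negative = finished early); *dark time* — the period with dimmed
room lights — is proxied by the actual cutting-phase (phase 2) duration
unless a dedicated `dark_time` field is present, since dim lighting is
essentially coextensive with that phase in minimally invasive and robotic
procedures. Summaries are complete-case with the exclusion count reported.
The schedule generator's defaults encode the qualitative pattern of a
gynecology OR programme (open procedures early and high-risk, minimally
invasive shortest and leanest-staffed, robotic longest-running and
overrunning).

## Problem sizes and numerical choices

Validation workloads are sized for a single CPU: classifier/oracle
agreement on 100 random scenes (≤5 persons, ≤200 frames), occupancy
recovery at jitter 2 px / dropout 5% averaged over 20 seeds, tracker
fidelity over 50 seeds of 300-frame scenes, Friedman null calibration at
2000 replicates, and questionnaire pattern rates over 500 seeds. Ties in
assignment are resolved by the Hungarian solver; determinism is guaranteed
by ordered processing (ascending frame, track id, detection index).
Degenerate inputs reject early: empty tracks, zero-length phases,
self-intersecting or empty zone polygons, matrices with missing cells or
fewer than 3 conditions.

## Known limitations

* The zone classifier is a binary table-activity rule; it does not
  recognise actions (instrument handovers, documentation work).
* The pixel displacement threshold is resolution- and frame-rate-specific;
  scenes at other scales need a rescaled threshold.
* The tracker has no re-identification: a person lost longer than
  `max_age` returns as a new identity.
* Synthetic validation bounds correctness, not field accuracy (see the
  scene-generator caveats above).
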