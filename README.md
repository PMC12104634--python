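# orpose

Operating-room staff activity analytics: who is working at the operating
table, when, and how that relates to perceived workload.

Hospitals studying how surgical technology (open vs minimally invasive vs
robotic-assisted surgery) affects intra-operative nurses need three data
streams analysed together: ceiling-camera video of the OR, workload/job
satisfaction questionnaires, and the hospital's scheduling records.
`orpose` implements the quantitative pipeline for all three:

* **Pose tracking** — per-frame 2D keypoint detections (COCO-17 layout,
  e.g. from a pose estimator) are associated into identity-stable tracks
  with a two-stage, confidence-split matcher: confident detections are
  matched to tracks first (optimal assignment on a blend of box IoU and an
  OKS-style keypoint similarity), and leftover tracks get a second chance
  against low-confidence detections.
* **Table-activity classification** — a person counts as *active at the
  operating table* in a frame iff both wrists are inside the annotated
  table area, both shoulders inside the shoulder area, and the head
  centroid inside the head area, **and** the mean shoulder/head
  displacement over a 5-frame window does not exceed 17.5 px (faster
  movement means walking past, not working). Missing keypoints make a
  frame *undetermined*, never inactive.
* **Phase metrics** — combined activity/interaction percentages per
  clinical phase (patient entry→incision, incision→closing, closing→exit),
  which may exceed 100% when several staff are active at once, and a
  movement percentage per procedure.
* **Questionnaire statistics** — the modified Surgery Task Load Index
  (six workload domains + job satisfaction, 0–20 scales, scored per
  surgery type and phase): complete-case filtering, phase/type sums,
  Friedman omnibus tests (tie-corrected χ²), Nemenyi post-hoc comparisons,
  and Kendall's W effect sizes.
* **Schedule metrics** — planned-vs-actual phase deviations, dark time,
  risk-class and staffing summaries per surgery type.
* **Synthetic data** — ground-truthed OR scenes, questionnaire responses
  and schedule records, so every stage is testable end-to-end without
  access to (private) recordings.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Run the whole pipeline on a simulated procedure (two nurses, active at the
table for 10–60% and 30–90% of the cutting phase respectively, 1 px
detector jitter):

```bash
orpose demo --seed 1 --out demo_out
```

```
demo pipeline complete; 2 tracks; outputs in demo_out
procedure_id surgery_type  phase  activity_pct  movement_pct  interaction_pct
     sim-000          MIS      1           0.0      6.464646              0.0
     sim-000          MIS      2         110.0      4.266667            110.0
     sim-000          MIS      3           0.0      6.400000              0.0
```

Reading the phase-2 row: the first nurse is active for 50% of the cutting
phase and the second for 60%, so their combined table occupancy is 110% of
the phase duration — the tracker recovered both identities from the noisy
detections and the classifier recovered the scheduled bouts. The small
movement percentages come from the walking the nurses do outside their
bouts. The same run writes the questionnaire analysis
(`surgtlx_by_type.csv` — e.g. mental demand differs across surgery types
with Friedman χ² = 11.76, p = 0.0028, W = 0.33 on this simulated cohort)
and the schedule summary (`schedule_summary.csv` — open procedures run
8.4 min early and robotic ones 15.8 min late on average, with the longest
dark time in robotic surgery).

Each stage is also available separately (`orpose simulate scene`,
`orpose track`, `orpose classify`, `orpose metrics`, `orpose surgtlx`,
`orpose schedule`), or as library functions:

```python
from orpose import build_tracks, classify_track, ActivityParams
from orpose.simulate import SceneConfig, simulate_scene, default_zones

detections, truth = simulate_scene(SceneConfig(
    n_staff=2, activity_schedule=[[(2, 0.1, 0.6)], [(2, 0.3, 0.9)]], seed=1))
tracks = [t for t in build_tracks(detections) if t.state == "confirmed"]
series = [classify_track(t, default_zones(), ActivityParams()) for t in tracks]
```

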