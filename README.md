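# glenokin

Glenohumeral kinematics from dynamic-MRI bone surfaces.

Dynamic MRI can image the shoulder in 3D while the patient actively abducts
the arm, yielding a short series of per-frame bone reconstructions (here an
8-frame, 28 s cycle, one frame every 4 s). From those segmented surfaces
this package computes the quantities that distinguish rotator-cuff disease
grades — in particular the joint's **looseness**: how much the humeral head
translates on the glenoid, and how much the subacromial space changes,
over an abduction cycle. It is written for musculoskeletal imaging and
biomechanics researchers who have per-frame labelled bone meshes (or want
to validate such a pipeline on synthetic data) and work mainly from Python.

## Method

Per shoulder sequence, with all lengths in mm:

1. **Glenoid coordinate system.** A least-squares ellipse is fitted to the
   glenoid rim contour (projected onto its total-least-squares plane). The
   ellipse's minor axis is the anterior-posterior axis **X**, the major
   axis the superior-inferior axis **Y**, **Z = X × Y**; the ellipse
   centre is the origin and X–Y span the glenoid plane. Axis signs are
   fixed by explicit superior/anterior hint points, so left and right
   shoulders need no mirroring.
2. **Registration.** Each motion frame is rigidly aligned to the 0°
   reference by point-to-point ICP on the scapula (closed-form SVD update
   per iteration, deterministic principal-axes initialisation), making the
   glenoid frame fixed across the cycle.
3. **Per-frame kinematics.** The humeral head centre (least-squares sphere
   fit) is projected perpendicularly onto the glenoid plane, giving
   (x, y); the subacromial space width **WSS** is the shortest distance
   between the superior proximal-humerus surface and the inferior acromion
   surface (symmetrised vertex-to-triangle minimum); glenohumeral
   abduction is the angle between the humeral shaft axis (first principal
   direction) and the glenoid plane.
4. **Looseness metrics.** Over the 7 measured frames: WSS_avg, WSS_range,
   Y_avg, Y_range, X_avg, X_range (avg = mean, range = max − min). A
   **WSS_range > 4 mm** flags a torn cuff (massive or full-thickness
   supraspinatus tear) versus normal/tendinopathy shoulders.
5. **Statistics.** Two-group comparisons use Student's t when both groups
   pass a Shapiro–Wilk screen and Mann–Whitney U otherwise (exact for
   small tie-free samples); multi-group comparisons use Kruskal–Wallis
   with Dunn post-hoc tests gated on the omnibus. An intra-observer
   repeatability harness reports extreme-value spreads over repeated
   measurements of one frame.

A synthetic shoulder generator (`glenokin.synthetic`) builds labelled
8-frame sequences from geometric primitives with analytic ground truth —
group-specific trajectories for normal (N), tendinopathy (TA),
supraspinatus-tear (SST) and massive-cuff-tear (MCT) shoulders — so every
stage is testable without patient data. See `docs/methods.md` for the
model details and its limitations.

## Worked example

```bash
python examples/analyze_synthetic_shoulder.py
```

generates one synthetic SST shoulder (8 frames, 0.2 mm surface noise,
random whole-frame perturbations) and runs the full pipeline:

```
frame  t(s)   x(mm)   y(mm)  WSS(mm)  abduction(deg)   [x%, y%]
    1     4    4.64    3.97     9.46             7.4   [  37.3,   22.7]
    2     8    5.58    4.50     9.89            14.8   [  44.8,   25.8]
    ...
    7    28    0.81    2.05     6.89            52.0   [   6.5,   11.8]

WSS  avg 7.12 mm, range 5.46 mm
Y    avg 2.00 mm, range 5.00 mm
X    avg 0.90 mm, range 9.29 mm
classification: tear  (WSS range > 4 mm -> tear)
```

Each row is one motion frame: the humeral-head centre on the glenoid
(mm and percent-of-rim units, the latter mapping every glenoid onto a
−100%…+100% circle), the subacromial width and the abduction angle. The
recovered metrics sit within measurement noise of this profile's
generating parameters (WSS 7.3/5.3, Y 2.0/5.0, X 0.9/9.3 mm), and the
large WSS range correctly flags the tear.

Other examples: `fit_glenoid_coordinate_system.py`,
`register_motion_frame.py`, `cohort_group_statistics.py`,
`repeatability_check.py`. A thin CLI wraps the same library:
`glenokin simulate|analyze|stats|repeatability` (see `--help`).

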