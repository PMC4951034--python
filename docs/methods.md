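# Methods

This note documents the models, numerical choices and known limitations of
glenokin. Units are mm, degrees and seconds throughout; all coordinates
live in the world frame of the reference scan (never voxels).

## Geometric fits

**Plane.** Total least squares via SVD of the centred points; the normal is
the least-variance direction. Degenerate inputs (< 3 points, collinear
within a 1e-12 relative singular-value ratio) raise. The sign is set by an
optional hint point, else deterministically (largest component positive).

**Glenoid ellipse and coordinate system.** The rim contour is projected
onto its best-fit plane and an ellipse-specific algebraic least-squares fit
(the numerically stable variant of the direct conic-constrained method) is
performed in-plane; this is deterministic and needs no initialisation,
which is why it was chosen over iterative geometric ellipse fitting. The
conic is converted to centre/axes; non-ellipse conics raise a fit-failure
error. In-plane axes are lifted to 3D: major axis → superior-inferior Y,
minor axis → anterior-posterior X, Z = X × Y. Signs come from explicit
superior and anterior hint points (axis · (hint − centre) > 0); the side
flag is metadata only, so left shoulders are handled by hints, not by
mirroring. Whether the in-plane projection happens before or after the
ellipse fit is an open modelling choice; projecting first keeps the fit a
well-posed 2D problem and is what this package does. If
semi_major/semi_minor < 1.02 a `NearCircularWarning` is emitted and the
eigenvalue ordering of the axes is kept: anatomical glenoids are elongated,
so near-circular contours usually indicate segmentation trouble rather
than anatomy.

**Sphere.** Linear algebraic fit (centre and radius from one least-squares
solve) followed by a few Gauss–Newton passes on the geometric residual
`| |p − c| − r |`; coplanar points raise. The refinement makes the result
agree with a full nonlinear least-squares solution to ~1e-6 on noisy caps.

**Shaft axis.** First principal direction of the shaft point cloud. The
anatomy gives no preferred fitting method for "the longitudinal axis"; the
principal direction is the simplest deterministic estimator and recovers a
cylinder's axis exactly. Clouds whose largest/second eigenvalue ratio is
below 4 raise an ambiguous-axis error (a sphere-like cloud has ratio ≈ 1,
a 120 × 12 mm shaft ≈ 17).

## Registration

Point-to-point ICP with nearest-neighbour correspondences (KD-tree) and a
closed-form Kabsch update per iteration. Initialisation is deterministic:
the best (by starting RMS) of identity, centroid shift and the four
proper-rotation principal-axes alignments — a reproducible stand-in for
interactive seeding. Convergence: RMS improvement < 1e-4 mm or 100
iterations (both configurable); an update that would increase the RMS is
rejected, so the recorded RMS history is non-increasing by construction.
Correspondence trimming is off by default (synthetic surfaces overlap
fully) and available as a fraction flag for partial overlaps.

Registration uses the **scapula region only**, and the recovered transform
is then applied to the whole frame. The scapula moves during
scapulothoracic motion, so aligning on it fixes the glenoid frame across
the cycle and isolates scapula-relative (i.e. glenohumeral) humeral
motion; registering whole reconstructions would blend humeral displacement
into the alignment.

## Kinematic measures

* Head projection: x = (c_head − c_glenoid) · X, y = ... · Y — the
  perpendicular projection onto the glenoid plane, so any offset along Z
  is invisible by construction.
* WSS: symmetrised vertex-to-triangle minimum distance between the
  superior proximal-humerus and inferior acromion surfaces (vectorised
  closest-point-on-triangle). Vertex-to-triangle is used instead of
  vertex-to-vertex to reduce discretisation bias; edge-to-edge contacts
  are still approximated by nearby vertex-face pairs, a bias that vanishes
  with mesh refinement. Point-set inputs fall back to the minimum pairwise
  distance. The operation expects explicitly labelled sub-surfaces; it
  does not search whole-bone contours.
* Abduction: arcsin(|d · Z|) ∈ [0°, 90°], the unsigned line-plane angle.
* Per an 8-frame cycle the reference frame is the registration target
  only; the 7 motion frames are measured (configurable via
  `reference_index`). Metrics: avg = arithmetic mean, range = max − min.
* Percent normalisation for trajectory plots is per-axis
  (x/semi_minor, y/semi_major, × 100) so every elliptical rim maps onto
  one −100%…+100% circle; an isotropic scale could not do that.
* Tear rule: strictly `wss_range > 4 mm` (threshold configurable).

## Synthetic sequences

The generator emulates the acquisition protocol (8 frames over 28 s, one
per 4 s, frame 0 = 0° reference) with primitive anatomy in a canonical
glenoid frame (X anterior, Y superior, Z lateral): head sphere r = 24 mm
(centre 26 mm lateral of the glenoid plane), shaft cylinder r = 12 mm and
length 120 mm, rim ellipse 17.5 × 12.5 mm, an asymmetric scapular blade
mesh (its waviness removes every symmetry, giving ICP a unique optimum),
and an acromion plate above the head. Dimensions are typical adult
anatomy, exposed as module constants, not claims about any dataset.

Trajectories: abduction ramps linearly from 0 to the group peak;
head-centre (x, y) and WSS follow sinusoids over the cycle. Since the
group-level summary statistics being emulated are statistics **of the 7
sampled frames**, the sinusoid is affinely calibrated so the 7 samples
have exactly the prescribed mean and max − min range (a raw sinusoid
sampled at 7 evenly spaced phases spans only ~97.5% of its amplitude,
which would systematically shrink every recovered range). Any smooth path
matching mean and range would do; the sinusoid phase is configurable
(default 0).

The acromion plate's height is set **per frame** to realise the prescribed
WSS exactly (plate height − head-top height, closed form; the exact sphere
pole is a mesh vertex so the discretised gap is exact too). In real
anatomy the acromion is rigid with the scapula and WSS changes because the
humerus moves and rotates under it; the per-frame plate is a deliberate
simplification that decouples the WSS trajectory from the head-centre
trajectory, as the emulated group parameters require. Default group
profiles: (WSS_avg, WSS_range, Y_avg, Y_range, X_avg, X_range) =
MCT (4.3, 4.0, 3.8, 6.4, −0.8, 9.2), SST (7.3, 5.3, 2.0, 5.0, 0.9, 9.3),
TA (10.4, 2.1, 0.3, 4.4, −1.6, 4.8), N (7.7, 1.9, 1.0, 3.4, 1.1, 3.5) mm,
with peak abductions 38/52/49/43°.

Each non-reference frame gets a random whole-frame rigid perturbation
(rotation sd 5°, translation sd 10 mm — large enough to exercise ICP,
inside its convergence basin) and every vertex isotropic Gaussian noise
(default sd 0.2 mm, the scale of segmentation error; intra-observer
spreads of repeated reconstructions are of order 1–2 mm, consistent with a
few tenths of a millimetre of surface noise per vertex after fitting).
Cohort generation adds between-subject jitter: additive Gaussian sd 0.3 mm
on the six trajectory parameters and 2° on peak abduction (sd
configurable; 0 gives identical same-group shoulders).

**What passing tests do and do not show.** The synthetic frames have exact
primitive geometry, complete surfaces, iid Gaussian noise and strictly
rigid inter-frame motion. Real reconstructions have anatomy-dependent
shape, partial/variable segmentation coverage, spatially correlated
segmentation error and through-plane blur. Parameter recovery on
synthetic cohorts therefore validates the computational chain
(registration → coordinate system → projection/distance/angle →
aggregation → statistics), not the clinical accuracy of dynamic-MRI
measurements.

## Statistics

Normality screen: Shapiro–Wilk at α = 0.05 per group (the choice of
screen is a documented default, configurable; constant samples fail the
screen by definition). Mann–Whitney is exact for combined n ≤ 20 without
ties, otherwise the tie-corrected normal approximation. Kruskal–Wallis
gates the Dunn post-hoc tests: pairwise z statistics on pooled mean ranks
with tie correction, two-sided normal p-values, unadjusted by default
(Bonferroni/Holm available via a flag) — adjustment conventions for Dunn
vary, so the default reports raw p-values and leaves the correction
explicit. All tests are two-sided. Under a normal null the screened
two-group chain rejects at ~5% (the exact Mann–Whitney branch is slightly
conservative at small n, pulling the rate marginally below α).

The repeatability harness mirrors a 6-repeat intra-observer protocol: one
intermediate frame is re-noised (fresh segmentation error) six times, each
repeat registered to a once-noised reference and measured; the spread is
max − min per quantity.

## Numerical conventions and edge cases

* Degenerate inputs raise typed exceptions (`DegenerateInputError`,
  `AmbiguousAxisError`, `RegistrationError`, `FitFailureError`,
  `MissingRegionError`) rather than returning NaNs.
* Deterministic outputs: all randomness flows through explicit seeds /
  `numpy.random.Generator`s; pipeline CSVs are written with fixed float
  formatting, so identical inputs give byte-identical files.
* Rotation validity is enforced at 1e-6 (orthonormality, det +1);
  recovered-vs-true rotation angles bottom out around 1e-5 degrees, the
  precision of arccos-based angle extraction.
* Sign conventions everywhere come from hints; absolute signs of X/Y
  averages are therefore convention-dependent, and only magnitudes and
  ranges are comparable across conventions.

## Problem sizes

Default meshes keep the pipeline interactive: scapula 221 vertices,
humeral-head cap ~290 points, superior cap 81 vertices, acromion plate 81
vertices, shaft 160 points, rim 72 points. One shoulder (7 registrations
+ measurements) runs in well under a second; the validation cohort (20
shoulders), the 2000-simulation test calibration and the 20-run
repeatability study each complete in seconds. Mesh density is a
resolution/cost trade-off: the WSS discretisation error at these defaults
is below 0.01 mm on the analytic sphere-plate case and shrinks
monotonically with refinement.

## Known limitations

* No Euler-sequence joint angles, scapulothoracic decomposition or
  velocity estimation — only the glenoid-frame translation, WSS and
  line-plane abduction.
* WSS requires labelled sub-surfaces; no automatic region extraction.
* ICP is point-to-point with no robust kernel; heavy outliers need the
  trimming flag or pre-cleaning.
* The tear rule is a fixed univariate threshold, not a fitted classifier;
  shoulders whose true WSS range sits at the threshold classify at chance
  under measurement noise.
* Non-rigid scapular deformation and image-space errors are outside the
  model.
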