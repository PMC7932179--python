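# Methods

This note records the model, the conventions and the deliberate design
choices behind `hdcmetrics`, in the spirit of a statistical-software
methods appendix. Units are millimetres, seconds and degrees throughout;
angles are held in radians internally. The tracker field frame has Z
pointing vertically up.

## Geometry

**Tip from pose.** The needle tip is P_tip = P_sensor + R·d, with R the
sensor orientation (stored as a scalar-first unit quaternion; matrix-dialect
input files are converted and re-orthonormalized on read, rejecting matrices
farther than ~1e-6 from a rotation) and d the fixed tip offset in the
sensor frame. Quaternions must be unit to 1e-6 or the pose is rejected.

**Plane fitting.** Skin and fistula planes are total-least-squares fits:
the normal is the smallest-singular-value right singular vector of the
centered point cloud, which minimizes the sum of squared orthogonal
distances. Collinear point sets (second singular value ≤ 1e-10 of the
largest) are rejected. Although any three of the four measured fistula
vertices determine a plane, the fit here uses all four: it removes an
arbitrary choice, is more stable under measurement noise, and reduces to the
same plane when the four are exactly coplanar.

**Sign conventions.** Plane normals have non-negative vertical component;
when the normal is horizontal to within 1e-9 the convention falls back
lexicographically (b ≥ 0, then a ≥ 0). This makes "above the skin" and
"top of the fistula" consistent across trials.

**Fistula frame.** The four measured vertices describe the mid-plane
rectangle of the straight vessel (whether the calibration touches the top
surface or the mid-plane is not observable from the data; mid-plane is
assumed, so the lumen circle of radius r is centered on the fitted plane's
axial line). The axial line joins the midpoints of the two short sides,
projected exactly onto the fitted plane; a quadrilateral whose opposite-side
mean lengths differ by less than a 1.5 : 1 ratio has no unambiguous long
axis and is rejected. The axis direction is oriented so its
largest-magnitude component is positive; the cross-section basis is
u_lat = n × â (lateral, x) and v_vert = n (vertical, y), giving a
right-handed (â, u_lat, v_vert) triad. Cross-section coordinates of a point
are its components along u_lat and v_vert relative to the axis, so
√(x² + y²) is exactly the distance from the axial line.

## Segmentation and the two clocks

Events are annotated in the camera clock; the camera-to-tracker delay is
assumed constant within a trial and estimated as the mean camera-minus-
tracker difference at the first two events, then subtracted from all four
camera timestamps. Each mapped event snaps to the nearest trajectory sample
(ties toward the earlier sample); samples outside [T₀, T₃] are discarded.
Boundary samples belong to both adjacent phases (closed intervals) so that
instantaneous quantities are consistent at the seams, while phase
*durations* use the mapped event times themselves, not the snapped sample
times. Automatic event detection from motion alone is deliberately out of
scope — annotations are required input, as in manual video review.

## Process metrics

- Path length is the raw sum of consecutive tip displacements over the
  closed phase range. Note that raw path length is biased upward by sensor
  noise (each step adds ~σ√2 per axis in expectation); this is a property
  of the metric definition, not of the implementation, and is visible in
  the synthetic cohorts.
- The insertion angle of a sample is the elevation of the tip as seen from
  the entry point: arctan of depth below the skin plane over the in-plane
  distance of the tip's skin projection from P_entry (the projection of the
  tip at T₀). It is *not* the shaft orientation of the 6-DOF sensor; the
  two coincide only for straight insertions through the entry point. The
  sign is positive below the skin plane. A sample vertically over the entry
  point contributes ±90°; a sample coincident with the entry point itself
  (exactly the T₀ sample in noiseless data) is undefined and is excluded
  from the average, with N reduced accordingly.
- The angle change rate is the mean of per-step finite differences divided
  by the sample count N; on uniformly sampled data this telescopes to
  (α_end − α_start)/(N·Δt), which the tests enforce to 1e-9.
- Start-point accuracy at phase start (T₀ for Phase 1, T₂ for Phase 3) is
  the distance between the tip's projection onto the fistula plane and its
  projection onto the axial line. Because the axis lies in the plane, this
  equals the in-plane distance to the axis.
- The lateral angle compares the start accuracy with the phase-end in-plane
  distance to the axis: arcsin(|a − d_end| / in-plane displacement),
  positive when the motion approaches the axis. The arcsin argument can
  exceed 1 when the tip path leaves the fistula plane (the formula
  implicitly assumes in-plane motion); it is clipped to 1 with a logged
  warning. Zero in-plane displacement leaves the angle undefined and raises.
- Phase 2 (rotation) produces no process metrics: the tip is nominally
  stationary while the needle rolls about its own axis.

## Outcome metrics

All outcomes are read on the cross-section disc of radius r. Infiltration
is entry-gated: the first sample with radial distance ≤ r marks lumen
entry; afterwards any sample with distance > r flags the phase containing
it (shared boundary samples attribute to the earlier phase, for the class
exactly as for the flag). Distance exactly r counts as inside — both for
entry and for success of the final position. The flagged phase is
classified *bottom* if the vertical coordinate at its maximal excursion is
negative, else *top* (y = 0 ties classify as top; the classification sample
is the maximal-excursion one, kept for audit). Phase-2 infiltrations are
tallied separately from the Phase 1/3 bottom/top table, which has no
rotation-phase column. Risk points are computed for every trial, infiltrated
or not, so cohort scatter plots show all trials against the lumen circle.

## Statistics

Normality of the paired Phase-1-minus-Phase-3 differences is tested with
Shapiro–Wilk at α = 0.05 (a standard choice at n ≈ 42; the gate is
configurable). If not rejected, a paired t-test is used; otherwise a
Mann–Whitney U test on the two phase samples. The U test is unpaired even
though the data are paired — this mirrors the original analysis protocol
and is kept for fidelity; a Wilcoxon signed-rank alternative is available
behind `use_wilcoxon`. No multiple-testing correction is applied across the
seven metrics by default; Holm is available behind `holm`.

The process→outcome model is a bivariate-response linear regression: each
predictor carries a 2-vector coefficient (effect on x and on y of the
phase's risk point). It is fitted as two independent OLS regressions on the
shared design (intercept + 7 predictors); the point estimates are exactly
those of a stacked formulation, and per-response inference matches the
phase-blocked p-value table layout. Each phase's own metrics predict its
own risk point. Rank-deficient designs raise a collinearity error naming
the offending columns. R² is reported in percent per response; p-values
below 0.001 print as "<0.001*", stars mark p < 0.05.

## The synthetic simulator

The generator emulates the physical rig, not any particular subject pool:
skin plane at z = 0, fistula axis along +X at a configurable depth
(default 10 mm — a 3 mm skin layer plus tissue above a 7 mm-radius vessel),
40 Hz sampling, a needle-tip sensor offset of 18 mm along the shaft.

A trial is a piecewise path: an above-skin approach (trimmed away), a
straight Phase-1 descent from the entry point at the configured insertion
angle with a lateral drift heading (positive drift toward the axis),
optional retract-and-reinsert cycles placed strictly before the lumen-entry
distance (vessel search happens before the vessel is entered), optional
overshoot past the bottom wall (planted Phase-1 infiltration), a stationary
Phase-2 with a 180° roll about the shaft, and a Phase-3 that dips and then
levels toward a configured final cross-section offset, optionally
overshooting beyond a lumen wall (planted Phase-3 infiltration, bottom or
top). Isotropic Gaussian noise (default σ = 0.05 mm, modeling residual
jitter after tracker filtering) is added to the tip track and sensor poses
are back-computed so P_sensor + R·d reproduces the noisy tip exactly.

Phase *durations* are the primary skill controls (the reference cohort
statistics are reported as durations and path lengths; speed falls out as
their ratio). Durations snap to the 0.2 s common grid of the 40 Hz tracker
and 15 fps camera, which places true event times on exact camera frame
instants: the annotation model assumes the reviewer marks the frame at
which each event is visible, so camera timestamps are frame times plus the
constant clock delay. Under this model the delay estimate is exact up to
the tracker's own sampling, and mapped events land within one 40 Hz sample
of truth. Sub-frame annotator error is *not* modeled; with independent
per-event frame-rounding errors (±33 ms), mapped-event accuracy would be
frame-limited rather than tracker-limited.

Ground truth per trial (event times, per-phase metrics, risk points,
infiltration flags) is computed from the noiseless path by generator-local
plain-loop arithmetic in the canonical frame, independent of the analysis
modules; the test suite closes the loop by recomputing everything through
the analyzer and requiring agreement to 1e-6.

Cohort generation draws per-subject latent skill offsets (0.7 of the
population SD between subjects, 0.7 within) for insertion angle, durations,
drift, entry offset, advance and camera delay, clipped to physical ranges;
error-event rates (Phase-1 overshoot 9/42, Phase-3 infiltration 15/42 with
bottom:top = 6:9, unsuccessful finals 6/42 — drawn within infiltration
trials, since a final position outside the lumen is itself an infiltration
sample) mirror the reference cohort's error pattern. Subjects approach
predominantly (85%) from one side of the fistula, which is what makes
start-point accuracy and lateral angle informative about the *lateral* risk
coordinate. Randomness is keyed by (seed, subject, trial) so any single
trial is reproducible in isolation.

A second generator bypasses trajectory synthesis entirely: it draws
process-metric vectors from configurable distributions and produces risk
points from a planted coefficient matrix plus Gaussian noise, for fast
statistical testing of the regression machinery (exact recovery at zero
noise, confidence-interval coverage, power on planted cells).

### What the simulator does and does not capture

It reproduces the task structure, the two-clock timing model, the geometry
of entry/flashback/leveling, retraction search, and wall-crossing
infiltrations with controllable rates. It does not model tissue
deformation, needle bending, force/haptics, EM field distortion or drift,
annotator sub-frame timing error, or learning across trials. Passing tests
on synthetic cohorts therefore validates the *measurement machinery* —
segmentation, geometry, metric arithmetic, detection logic, statistics —
not the clinical validity of the metrics on human data.

## Numerical choices

- Event snapping ties break toward the earlier sample.
- Zero-length in-plane displacement, zero-duration phases, all-coincident
  trajectories and never-entered trials raise typed errors or return
  explicit "never entered" results rather than NaNs.
- The boundary of the lumen circle is inclusive (distance exactly r is
  inside) for entry, infiltration and success alike.
- Angle arithmetic uses arctan2; the arcsin argument of the lateral angle
  is clipped to [0, 1].
- Problem sizes in the test and acceptance runs (42-trial cohorts, 100–1000
  replicate oracle scans, 500–2000 statistical replicates) were chosen to
  hold Monte-Carlo error comfortably below the asserted tolerances while
  keeping the default suite fast.

## Known limitations

- The insertion angle conflates tip elevation with shaft orientation (by
  definition of the metric); a shaft-orientation variant from the full
  6-DOF pose would be a natural extension but is not implemented.
- The average-velocity metric is the ratio PL/t, which equals the mean of
  per-step speeds only under uniform sampling.
- Pooling 42 trials from 7 subjects ignores within-subject correlation;
  a mixed-effects extension is out of scope.
- Phase-1 start accuracy at T₀ and Phase-3 start accuracy at T₂ use the
  same projection formula even though the needle is inside tissue at T₂.
- Raw path length and the angle change rate are sensitive to sensor noise
  (the former through step-wise rectification, the latter through the
  near-entry samples whose elevation angle is ill-conditioned).
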