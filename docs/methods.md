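# Methods

This note records the models, numerical choices and known limits of the
spinecurve pipeline, in the order the data flows through it.

## Scan model and conventions

A scan is a regular grid indexed by (v, u): v counts laser profiles along
the scanner translation (the X axis, caudal → cranial), u counts samples
along each profile (the lateral Y axis).  Z is depth, positive from the
back toward the camera.  With this orientation the posterior median
furrow is a local *minimum* of Z along Y, so the transverse curvature
K = Z″/(1+Z′²)^{3/2} is **positive** in the furrow and negative on the
convex bulk of the torso — the sign convention every later stage relies
on.  Dropouts are carried in a validity mask; invalid cells never
constrain coordinates.  Rigid rotation of the patient about X is modelled
by rotating each profile's (Y, Z) points and linearly resampling onto the
row's original uniform Y grid, so the surface remains a graph Z(Y); cells
leaving the rotated span become invalid.

## Synthetic back generator

The generator is the package's test instrument: it emulates the scanner's
sampling (0.9 mm profile spacing over ~630 mm, 1 mm lateral sampling over
300 mm, 0.1 mm Gaussian depth noise) and the back morphology the method
exploits.  The surface is

    Z(X, Y) = torso(Y) + s(X) − d(X)·exp(−(Y − c(X))² / 2w²) + ε

* `torso(Y)`: elliptic section, half-width 200 mm, depth 40 mm → apex
  radius of curvature a²/b = 1000 mm, so the furrow's curvature
  (d/w² = 4/100 = 0.04 /mm) dominates the background by ~40×;
* `s(X)`: smooth sagittal offset, default a cubic giving a ±3.75 mm
  double-S (kyphosis/lordosis) shape;
* `c(X)`: the ground-truth lateral centerline, default a cubic with
  ~±9.5 mm scoliotic deviation;
* `d(X)`: furrow depth 4 mm, tapering linearly to 30% over the cranial
  quarter of rows — the real furrow fades above the shoulder blades,
  which is what forces the ROI reduction in X before RMSD comparison;
* `w`: furrow half-width 10 mm; ε: iid N(0, 0.1 mm) on Z only.

The furrow depth and width are not published quantities; 4 mm / 10 mm are
package choices producing a furrow of realistic visual prominence.  The
brightness channel carries the marker line,
`1 − c_m·exp(−(Y − c(X) − o)²/2w_m²)`, with contrast 0.95, half-width
6 mm and lateral offset `o` emulating palpation error (0 by default).
The marker half-width must exceed ~4.4 mm for the line to stay inside the
0.08–0.15 detection window after the 7×7 smoothing (see below); 6 mm
corresponds to a drawn line a centimetre wide, consistent with marking a
~10 mm-wide spinous process.  What the generator does *not* model:
breathing/sway during one sweep, skin-fold asymmetry, shoulder-blade
relief (tests add Gaussian bumps explicitly where needed), laser
speckle, or occlusion dropouts (tests punch holes in the mask directly).
Passing recovery tests therefore demonstrate correctness of the
*algorithms* under the stated noise model, not clinical accuracy on real
backs.

## Curvature estimation

Derivatives are 3-point central differences with non-uniform-spacing
weights, applied per contiguous valid run (≥ 5 samples); run endpoints
are flagged invalid.  On a circular arc sampled at 1 mm this reproduces
1/R to 10⁻⁴ relative — far inside the 1% target — so the discretization
is never the accuracy bottleneck.

Depth is pre-smoothed with a 1-D Gaussian before differentiation
(`presmooth_sigma`, default **5 samples**, 0 disables).  The default is a
matched-scale choice, not cosmetic: second differences amplify the 0.1 mm
sensor noise to ~8×10⁻³ /mm at σ=2, which exceeds the lateral variation
of the furrow's own curvature profile near its apex
(K₀·Δu²/2w² ≈ 2×10⁻³ /mm over 3 columns), so the per-row maximum wanders
by several columns and track linking shatters.  At σ=5 — half the furrow
half-width, the standard detection scale for a ridge of that width — the
curvature noise drops to ~8×10⁻⁴ /mm against a smoothed ridge amplitude
of 4/(w²+σ²) ≈ 0.032 /mm, and the furrow is found on essentially every
row.  The smoothing widens the ridge (w² → w²+σ²) but does not move its
center on symmetric profiles, which is what the sub-pixel stage
estimates.  For analytic accuracy tests (circles) smoothing is disabled,
since the σ²-scale bias on a tight arc would dominate the measurement.

## Detection and linking

Per row, every local maximum of curvature strictly above the threshold
(default 0: keep all candidate ridges) is refined by a least-squares
quadratic over a 5-point window; if the fitted parabola opens the wrong
way or its vertex escapes the window, the discrete extremum is kept and
flagged.  Detection strength is the measured extremum value, not the
fitted vertex value — a one-pixel dip fits poorly but its depth is still
what thresholding should see.

Linking walks rows in increasing v.  Open tracks extend in seniority
order (longest first), each taking the unused detection nearest its tail
within `max_jump` = 3 columns; leftover detections open new tracks;
tracks silent for more than `max_gap` = 5 rows close; gaps inside a track
are bridged by linear interpolation and flagged; tracks spanning fewer
than `min_length` = 20 rows are dropped.  Seniority is the one refinement
over plain nearest-neighbour association: it prevents one-row noise
maxima from stealing the tail of the long furrow track, and on noisy
full-size scans reduces the candidate family from hundreds of fragments
to the handful of real ridges.

Curve selection replaces the operator's mouse click with an explicit seed
point: the candidate minimizing perpendicular distance to the seed wins;
ties go to the longer, then the stronger candidate.  This makes the two
operator-dependent inputs (ROI, click) scriptable parameters, so the
inter-operator experiment is reproducible.

The manual detector smooths brightness with a Gaussian of σ = 1.5 samples
truncated at 2σ (7×7 support), takes the per-row global minimum (the
marker is the darkest feature by construction; all-local-minima search
would only add candidates to reject), accepts it when below the intensity
threshold (default 0.10, midpoint of the 0.08–0.15 range), refines
sub-pixel, and closes gaps by 1-D interpolation.  A consequence worth
stating: a Gaussian line of contrast c smoothed laterally by σ has
minimum 1 − c·w_m/√(w_m²+σ²) > 1 − c, so contrast must exceed the
threshold's complement with margin — a 0.9-contrast line can never pass a
0.10 cut, while 0.95 does for w_m > 4.4 mm.  The detector raises a
descriptive error rather than fabricating a curve.

## Lifting and smoothing

Lifting reads X, Y, Z off the grid at each row's sub-pixel u by linear
interpolation along the row only (v is integral by construction); rows
with invalid bracketing cells are dropped and reported.  Smoothing fits
least-squares cubic splines with uniform interior knots every 30 mm to
Y(X) and Z(X) independently (the frontal and sagittal planes are analyzed
separately throughout), evaluated back at the original X.  30 mm resolves
the ≤ 4 anatomical curvature lobes over a ~500 mm thoraco-lumbar span
while averaging ~33 profiles of point noise, and a spline basis avoids
Runge oscillation by construction.  Smoothing happens in 3D space (on the
lifted curve), not in image space.  The operation is idempotent and
reproduces exact cubics to machine precision.

## Comparison and repeatability statistics

RMSD is computed after reducing both curves to their common X interval
and resampling at the manual curve's profile rows, so every summand is a
difference of two points in the same row; frontal and sagittal RMSDs use
the identical row set.  Summary statistics use the population SD
(divisor n) — the convention that reproduces the reference tables'
printed SD values (divisor n−1 gives 1.51/0.44 against the printed
1.48/0.43).  Values are rounded to 2 decimals only at presentation.

Repeatability over repeated (manual, automatic) pairs: at each X of the
span common to all repeats, the SD across repeats of the manual
coordinate (posture variability) and of the per-repeat manual−automatic
difference (method variability), per plane; scalar summaries are means
over X.  In the curve-level repeat simulator each repeat draws one rigid
posture shift per plane shared by both curves plus independent per-row
detection noise on each curve, so the expected per-X SDs are
√(posture²+detection²) and detection·√2.  Because the posture shift is a
single draw per repeat, the per-X SDs are fully correlated across X and a
20-repeat experiment estimates the posture SD with ~16% sampling spread;
validation therefore pools three independent experiments by RMS before
comparing against the generating values.

## Rotation-invariance checks

Curvature is a property of the profile section, independent of its
orientation in the Y–Z plane, so detection must tolerate the patient
leaning differently against the rest.  After rotating a scan about X,
detected coordinates live in the rotated frame; a 5° roll moves the
furrow laterally by |Z|·sin 5° ≈ 3.5 mm rigidly.  The invariance check
therefore maps the detected curve back with the inverse rotation before
differencing — the residual (≈ 0.18 mm RMS at ±5°, noise-free) measures
resampling and detection error only, which is the meaningful invariance
statement.

## Known limitations

* The method finds the *surface* expression of the spine; vertebral axial
  rotation is invisible to it, so its curves are not interchangeable with
  X-ray centerlines.
* Near the neck the furrow fades and detection degrades; the automatic
  curve is honest about its coverage and comparisons are restricted to
  the common span rather than extrapolated.
* The greedy linker is deterministic but local; pathological crossings of
  equally strong ridges closer than `max_jump` columns could swap tracks.
* Real marker lines are ink strokes with hard edges, not Gaussians; the
  detectability bound above is exact only for the synthetic model, though
  the qualitative contrast/threshold trade-off carries over.
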