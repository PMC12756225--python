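# Methods

This note documents the models, numerical choices and limitations of
`metastim`. It describes what the code computes; every number quoted here
is produced by the test suite or `scripts/acceptance.py` at run time.

## Orientation parameterization

Surface pose is (slant σ ∈ [0°, 90°), tilt τ ∈ [0°, 360°)), with unit
normal **n**(σ, τ) = (sin σ cos τ, sin σ sin τ, cos σ) — the standard
spherical form, so the frontoparallel plane has normal (0, 0, 1). Tilt is
measured counter-clockwise from screen-right, matching the touchpad
convention τ = atan2(y, x). Tilt is reported as undefined below
`slant_epsilon` = 0.1°, where the normal's frontoparallel projection is
numerically meaningless. All public interfaces use degrees; radians are
internal.

Cue-conflict configurations are split symmetrically around the central
pose: the disparity cue takes (σ_c − Δσ/2, τ_c − Δτ/2) and the texture
cue (σ_c + Δσ/2, τ_c + Δτ/2). With this sign choice the disparity cue is
always the one closer to frontoparallel, which is what gives the tilt
manipulation its leverage on relative cue reliability.

## Constrained vector-sum weight estimation

Three solvers share one reduced parameterization. Both constraints —
unit norm of the combined vector and alignment with the percept — depend
only on the pairwise dot products a = **n**_p·**n**_t, b = **n**_p·**n**_d,
c = **n**_t·**n**_d, so all iterations run in that 2-unknown scalar space.

* **Pseudo-inverse**: ordinary least squares on the 3×2 system; no norm
  constraint, reported with the 3-vector residual.
* **Closed form**: valid when the percept lies in the cue plane (scalar
  triple product below `tol_plane` = 1e-9). The alignment line is then
  tangent to the unit-norm ellipse and the tangency point solves the 2×2
  Gram system [[1, c], [c, 1]] w = (a, b). `line_ellipse_intersections`
  exposes the substituted quadratic and its discriminant as an
  independent diagnostic.
* **Levenberg–Marquardt** (`scipy.optimize.least_squares`, method "lm",
  analytic Jacobian): minimizes the two squared constraint residuals,
  equally weighted. Initialized at the pseudo-inverse solution
  renormalized onto the ellipse — cheap and inside the attraction basin.
  Non-convergence returns the best iterate with a flag rather than
  raising, so batch pipelines never abort.

A vectorized damped Gauss–Newton version (`estimate_batch`) processes
whole trial tables with explicit 2×2 linear algebra and per-row damping;
it is tested to agree with the per-trial SciPy route to ~1e-7.

Numerical caveat: at the tangency the constraint Jacobian is singular
(the line is the ellipse's tangent), so the sum of squares grows
quartically along the tangent direction and *parameter* accuracy of any
residual-driven optimizer is limited to ~√ε ≈ 1e-8–1e-7 in float64 even
though the residuals themselves reach ~1e-16. The closed form does not
suffer from this and is used as the oracle.

Degenerate inputs: cue separations below `tol_angle` = 0.5° make the
weights unidentifiable (any pair with the right sum works); the
symmetric pair (0.5, 0.5) is returned with a `degenerate` flag. Negative
weights are legitimate solutions (percept outside the cue wedge) and are
never clipped — clipping would bias pre/post difference tests toward
zero.

## Stimulus geometry

Screen-centered frame: x right, y up, z toward the viewer, eyes at
(±IPD/2, 0, VD). Defaults: VD = 50 cm (55 cm available as a plain
override, since display distance varies between setups), IPD = 6.4 cm,
aperture 35.5° of visual angle. The metastimulus pipeline is: texture a
plane with jittered-grid Voronoi sites (cell centers ± jitter/2 cell
widths per axis, deterministic per seed), cast each texture point along
its cyclopic ray onto the disparity plane (ray–plane intersection), then
project through each eye onto the screen plane (off-axis frusta, zero
disparity on the screen, crossed disparity positive by convention).
Geometry operates on points; rasterized rendering (PNG/anaglyph export)
is cosmetic. The defining invariant — the cyclopic image is independent
of the disparity pose, while the disparity field depends on the
disparity pose alone — is property-tested.

## Synthetic observer

No public response data exist for this paradigm, so the package ships a
generative observer whose purpose is to give the analysis something with
the right *structure*, not to mimic any human dataset:

* Generative disparity weight
  w_d = intercept + slope·ln σ_c + gain·τ_c (+ interaction·τ_c·ln σ_c),
  defaults intercept 1.6, slope −0.25 per ln-degree, gain 0.002 per
  degree, interaction 0. These directions (down-weighting of disparity
  with slant, up-weighting with tilt) match the qualitative pattern
  reported for human observers; the magnitudes are free parameters that
  keep w_d within (0, 1.5) on the tested grid.
* The mean perceived normal is the vector sum at that w_d, with w_t
  chosen on the unit-norm ellipse — so noiseless simulation followed by
  estimation closes exactly (max cell error ~1e-14 in practice, bound
  1e-6 in the tests).
* Response noise is von Mises–Fisher on the sphere, sampled by the exact
  inverse-CDF for the polar cosine in 3D. Default concentration
  κ = 150 (≈ 4.7° mean angular error), a precise-but-human-plausible
  adjustment observer; calibration and recovery studies use κ = 50
  (≈ 8°) to represent a noisier observer.
* Subjects get Gaussian random intercepts on w_d (SD 0.05 by default);
  this mirrors random-intercept heterogeneity without importing a mixed
  model.
* Post-training adaptation is an additive shift on w_d (default −0.25)
  applied only to the joint-control (ATD) group, emulating reweighting
  toward texture. The shift size was fixed so that the full 3×3×2 cell
  grid shows the effect robustly at the default noise level, making the
  all-cells-significant / controls-null contrast a stable property of
  the preset rather than a seed accident.
* The touchpad adjustment dynamic walks the surface pole 0.1°/frame in
  the direction of touches beyond 0.7 pad radius (quadrant-aware
  atan2(y, x); a single-argument arctangent cannot distinguish opposite
  tilts).

What the synthetic observer does **not** model: reliability-weighted
(MLE/Bayesian) cue combination — deliberately outside the vector-sum
framework — response lapses, learning within a session, motor noise in
the adjustment loop, or any fitted correspondence to human variance
components. Passing tests therefore certify the estimator and inference
machinery, not claims about human data.

## Inference

* **Trend fit**: OLS of per-subject cell-mean w_d on ln σ_c with
  categorical tilt offsets, pooling discrepancy conditions. Intervals
  come from a subject-level nonparametric bootstrap (default 1000
  resamples; percentile 95% CI), deterministic under the seed.
* **Pre/post test**: per-subject cell differences (post mean − pre mean)
  enter a paired sign-flip permutation test (t statistic; zero-variance
  cells map 0/0 to t = 0). Raw p-values use the cell's own permutation
  distribution; family-wise control uses the max-T distribution over the
  9 cells of each discrepancy condition, which respects the cells'
  correlation structure. p = (1 + #{|T*| ≥ |T|}) / (n_perm + 1), so
  adjusted ≥ raw and p > 0 always. Default n_perm = 10,000; the
  calibration studies use 999.
* Degenerate trials are excluded from cell means and counted in the
  weight map and run manifest.

The per-trial weights can be aggregated to cell means (as here) or used
trial-wise; the package exposes the trial table so either route is open.

## Problem sizes

The shipped studies use 10 subjects × 90 judgment trials × 2 phases.
Calibration uses 1,000 null simulations at n_perm = 999 (measured raw
rejection rate ≈ 0.053 at nominal 0.05); slope-recovery coverage uses
100 replicate studies with 500 bootstrap resamples each (measured
coverage 95%, threshold 90%). These sizes give binomial/bootstrap errors
small enough for the stated checks while keeping a full run in minutes.

## Known limitations

* The weight estimator assumes both cue normals are known exactly; cue
  miscalibration in a real rig propagates directly into the weights.
* With percepts far off the cue plane the two-constraint least-squares
  compromise has no perceptual interpretation guarantee; the residual
  norm should be inspected (the pipeline carries it per trial).
* The max-T family is defined per discrepancy condition (9 cells); a
  global family over all 18 cells would be stricter.
* The generative w_d model is linear in ln σ_c and τ_c; it cannot
  express saturation or cue vetoing at large conflicts.
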