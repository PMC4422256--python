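# Methods

This note documents the models and numerical choices behind `dyssync`:
what the synthetic data emulate, how each quantity is defined, which
defaults matter, and what the validation suite does and does not show.

## The phantom

### Geometry

The LV myocardium is the shell between two coaxial ellipsoids truncated
by a flat valve plane. World conventions: long axis = +z, epicardial
apex at z = 0, valve plane at z = L; the anterior RV-insertion reference
direction is +x. Defaults (mm): endocardial semi-axes (30, 30, 62),
epicardial (38, 38, 70), truncation fraction 0.75 (L = 105 mm), giving
an end-diastolic cavity of ≈ 205 ml and an 8 mm mid-ventricular wall —
a dilated, heart-failure-scale ventricle. Surfaces are triangulated
ellipsoid patches (96 circumferential × 48 longitudinal rings by
default); the endocardium is closed with a flat basal cap so cavity
volumes are well defined.

### Motion

Motion is Lagrangian and separable: every material point moves as
`u(x, t) = A(x) · g(t − τ(x))` with

* `g` a raised cosine, 0 → 1 → 0 over an activation window of
  `activation_duration_frac` × cycle (default 0.5 × 1000 ms), so a
  segment with onset delay τ peaks at τ + 250 ms;
* `τ(x)` piecewise-constant per AHA segment, blended linearly over 5°
  at sector boundaries and over 4% of the long axis between rings so
  the displacement field is continuous (no tearing);
* three motion components: radial contraction, twist (linear from
  `twist_deg` = 8° at the apex to 0 at the base), and longitudinal
  shortening (12% of the apex-to-base distance, base fixed).

The radial map is cavity-anchored: points at or inside the end-diastolic
endocardial radius scale by (1 − A·a(t)) (A = `contraction_amplitude`,
default 0.25), while points outside it move so that in-plane annular
area is preserved. The inner wall therefore moves inward more than the
outer wall and the wall *thickens* during contraction, as real
myocardium (nearly incompressible) does; a uniform radial scaling would
thin the wall and invert the thickening-based indices. The endocardial
surface itself keeps the simple (1 − A·a) scaling, so cavity-volume
ground truth is unaffected by this choice.

The temporal shape of regional contraction is not constrained by any
measurement here; the raised cosine is a stand-in chosen because its
peak time is exact and its smoothness makes sub-frame peak
interpolation well-posed.

### Ground truth

`true_segment_peak_times` are **not** the closed form τ + T_act/2: they
are obtained by evaluating the same wedge-volume functional the
pipeline measures (signed tetrahedra of the deformed endocardial mesh,
antialiased AHA binning in the fixed ED frame) on a dense 512-point
time grid with parabolic refinement. This matters because twist and the
sector blending move small amounts of material across fixed wedge
boundaries, shifting true minima by a few ms relative to the closed
form; defining truth through the same functional keeps the
"truth vs. pipeline" comparison free of definitional bias. The
ground-truth SDI is then the sample SD of those peak times as % of
cycle.

Two presets bracket the clinical range: `volunteer_params` (Gaussian
delay jitter, SD 40 ms → SDI ≈ 3–4%, the scale seen in healthy
subjects) and `dyssynchronous_params` (free-wall half of the segments
delayed 200 ms → SDI ≈ 10%, just above the 9.75% cut-off, an LBBB-like
activation pattern).

### Rendering

Untagged (SSFP-like) stacks: piecewise-constant tissue classes (blood
1.0, myocardium 0.35, background 0.05) sampled at voxel centers by
inverting the motion map (fixed-point iteration), plus seeded additive
Gaussian noise. The default voxel size is the clinical protocol's
2.2 × 2.2 × 10 mm with 30 phases. Tagged (CSPAMM-like) stacks carry a
product of two orthogonal sinusoidal gratings of 7.7 mm period
evaluated at material coordinates, i.e. the tags deform with the
tissue; blood and background carry no tag signal. No MR physics is
simulated (no banding, no tag fading, no k-space).

### Cohort simulator

One row per patient. A latent dyssynchrony class (58% prevalence)
selects a truncated-normal SDI distribution on either side of the 9.75%
cut-off (15.2 ± 5 above, 6.5 ± 2 below, in %); reverse remodelling is
Bernoulli with probability 27/29 above and 8/21 below the cut-off —
the generative link matches the dichotomized proportions of the second
published cohort, and covariate distributions (QRS 146 ± 21 ms,
morphology 28/4/18 LBBB/RBBB/IVCD, scar in 42% with burden 24 ± 11%,
ESV 172 ± 82 ml) mirror that cohort's table. Post-CRT ESV and the
walk/NYHA/QOL deltas are drawn *conditionally on the drawn outcome
flags* so that the ≥ 15% ESV rule and the 2-of-3 clinical rule
reproduce them exactly. The simulator therefore tests the analysis
chain's correctness and calibration, not its robustness to
model misspecification: covariates are mutually independent given the
outcome, which real registries are not.

## Geometry and regional measures

* **AHA 16 segments.** Longitudinal thirds divide the apex→valve
  distance equally; basal and mid rings get six 60° sectors, the apical
  ring four 90° sectors. Angle 0 is the RV-insertion direction,
  increasing counterclockwise viewed from the base; the apical quadrant
  containing angle 0 is segment 14 (septal). The apical cap
  (segment 17) is not used.
* **Regional cavity volumes** are signed-tetrahedron sums of the closed
  endocardial mesh about a fixed point at mid-height of the long axis.
  Faces are *softly* assigned to wedges: sector and third boundaries
  are linear ramps of half-width 3° / 0.04 of the long axis rather than
  hard cuts. With hard cuts, whole mesh rings cross the third
  boundaries simultaneously as the ventricle shortens, producing ~1%
  jumps in the wedge curves that corrupt the minima by 10–15 ms; the
  antialiased assignment makes the curves continuous in time while
  keeping the 16-wedge sum exactly equal to the total volume (weights
  sum to one per face). The partition frame (axis, sectors) is the ED
  frame at every phase.
* **Wall thickness** is the endo→epi nearest-surface distance per
  endocardial face, area-weighted per segment. It is directional by
  definition (swapping the roles changes the value); coincident
  surfaces give zero. Exact point-to-triangle distances are computed
  in-package (`_proximity`, KD-tree-pruned Eberly algorithm) because
  the installed trimesh lacks the rtree backend its own proximity
  queries require.

## Mechanics

Deformation fields are ED-referenced (`v(x, p)` = displacement of the
material point at ED position x, in mm) and sampled on regular grids.
Strain is projected Green–Lagrange: `F = I + ∇v` by central differences
(one-sided at boundaries), `E = ½(FᵀF − I)`, projected on local
radial/circumferential/longitudinal triads evaluated at ED and held
fixed. Green–Lagrange is exactly rotation-invariant, which the rigid
rotation test exploits; an engineering (linearized) strain would not
be. The radial frame direction is the nearest epicardial face normal;
the "combined" strain is the per-voxel mean of the three directional
strains. Segments with fewer than 10 field voxels are flagged missing.

**Time to peak.** Volume peaks at its minimum; thickness and radial
strain at their maximum; circumferential and longitudinal strain at
their minimum; combined strain at its largest absolute excursion. The
discrete extremum is refined by locating the extremum of a cubic-spline
interpolant within two frames (a local parabola, the more common
choice, is biased by up to ~10 ms at 30 frames because the curves are
cosine-like rather than quadratic near their extrema — enough to break
sub-0.1-point SDI recovery). Ties go to the earliest extremum; curves
whose range is below 0.5% of their ED value are declared peakless and
excluded. The peak search spans the whole cycle (not gated to systole);
with a different convention the index of strongly post-systolic
segments would change.

## Registration

Steps: (i) per-slice rigid in-plane realignment by sub-pixel phase
correlation; (ii) serial-propagation deformable registration of every
phase to ED; (iii) quantitative tracking quality.

The deformable transform is a cubic B-spline free-form deformation
(default knot spacing 14 mm, 2 resolution levels, coefficients shared
across levels in world mm). The objective per phase is

```
Σ_x  w(x)·(U_p(x+u) − U_0(x))² + (1 − w(x))·(T_p(x+u) − T_0(x))²  + λ·R(c)
```

over a region of interest within 12 mm of the myocardium, where U/T are
the untagged/tagged channels, `w(x) = 1/(1 + exp(d(x)/σ − 2))` with d
the distance to the endo/epi border voxels and σ = 1 mm — so border
motion is driven by the bright-blood contrast and mid-wall motion by
the tag pattern — and R is a bending-energy-like penalty (mean squared
second difference of the coefficient lattice, λ = 10⁻³; normalizing per
coefficient keeps λ meaningful across lattice sizes). Optimization is
L-BFGS-B with the analytic gradient (adjoint of the tensor-product
B-spline interpolation); each phase is initialized from the previous
phase's converged coefficients (serial propagation), which is what
makes the large mid-cycle displacements tractable. Non-convergence
degrades to a best-effort field with a per-phase report rather than an
error.

Known limitation: the FFD cannot represent the near-discontinuous
displacement across the 5° activation-boundary blend, so the endpoint
error concentrates there (~1–3 mm mid-cycle at 2 mm voxels against
≈ 8 mm true displacements). This biases the recovered SDI low by about
1 percentage point on the standard phantom — within the 2-point
qualification bound, and visible in the manifest QC.

Tracking quality replaces subjective visual scoring: mean symmetric
surface distance between propagated and reference endocardial surfaces,
and Dice overlap of the enclosed volumes on a 3 mm grid.

## SDI

Sample (n−1) standard deviation of the usable per-segment peak times,
divided by the cycle length, × 100. The population-SD variant is a
switch (`ddof=0`) for sensitivity analyses; at 16 segments the two
differ by a factor √(16/15) ≈ 1.033. Segments with no detectable peak
are excluded; fewer than 14 usable segments (of 16) make the index
indeterminate rather than silently less reliable. Dichotomization at
the cut-off is strict (`> 9.75%`); a patient exactly at the cut-off is
classified below.

## Statistics

* **Reverse remodelling**: ESV reduction ≥ 15% (inclusive). **Clinical
  response**: ≥ 2 of {walk +10%, NYHA −1, QOL −20%}, all inclusive.
* **ROC**: empirical curve over all distinct thresholds, trapezoidal
  AUC (equal to the Mann–Whitney statistic, which the tests verify by
  brute force). The optimal cut-off maximizes Youden's J, ties broken
  toward higher specificity, and is reported as the midpoint between
  the adjacent observed scores so the strict `>` rule reproduces the
  selected operating point.
* **Prevalence ratios**: log-link Poisson working model on the binary
  outcome (IRLS via statsmodels) with the HC0 sandwich variance (HC1
  available); 95% CI = exp(β ± 1.96·SE), Wald p. With one binary
  exposure and no covariates this reproduces the crude risk ratio
  exactly (algebraic identity, tested). PRs are preferred to odds
  ratios here because response is common (~50–70%).
* **Fisher's exact test**: two-sided by the point-probability
  convention (sum of hypergeometric probabilities ≤ the observed
  table's), the convention of mainstream statistical software; the
  doubling convention can differ and is not offered.
* **Bland–Altman**: mean difference, SD, limits of agreement
  (± 1.96 SD); per-pair coefficient of variation = sample SD of the
  pair / pair mean × 100, summarized mean ± SD; zero-mean pairs are
  excluded with a warning.
* **Dichotomized response model**: exposures are SDI > 9.75%,
  QRS ≥ 150 ms, LBBB vs. non-LBBB, scar burden > 14.7%; univariate PRs
  for each plus one joint model with all four. The published adjusted
  estimates from patient data are not recomputable without the data;
  the package instead demonstrates calibration on simulation (mean
  estimate within Monte-Carlo error of the generative PR; CI coverage
  95 ± 2% at n = 500 × 1000 replicates, with a common outcome — 40%
  unexposed / 80% exposed — because for rare outcomes the crude-ratio
  estimator's O(1/n) bias exceeds the Monte-Carlo error at that
  replicate count and the check would measure bias, not calibration).

## Problem sizes and determinism

The validation suite exercises the full pipeline on a reduced problem:
10 cardiac phases rendered at 1.7 mm isotropic (55 × 55 × 72 voxels,
chosen as a ~64³-scale grid that keeps a registration run under two
minutes on one CPU) against 30 phases at protocol resolution for the
phantom-only checks. Every random draw — rendering noise, cohort
simulation, Monte-Carlo calibration — flows from explicit integer
seeds; the pipeline manifest records SHA-256 checksums of all outputs
and identical seeds give identical checksums (the YAML config file is
the only output that records the run directory path).

## What passing tests do and do not show

The phantom validates the *measurement chain*: segmentation-free
geometry, registration, strain, peak detection, SDI, statistics. It
does not contain papillary muscles, through-plane slice misalignment,
tag fading, intensity inhomogeneity, arrhythmic beat-to-beat
variability, or regional scar akinesia; registration accuracy on real
CMR will be worse than on this phantom, and the ~1-point SDI bias of
the registration path should be read as a lower bound on real-data
error. The cohort simulator validates the *analysis chain* under its
own generative assumptions, not the epidemiology of any real registry.
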