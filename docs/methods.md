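# Methods

## Problem and measurement model

Elevated intracranial pressure (ICP) transmitted along the optic nerve
sheath swells the optic nerve head and deflects peripapillary Bruch's
membrane (BM) toward the vitreous. `onhvol` quantifies both effects from a
radial OCT scan pattern: six B-scans through the nerve head at 30°
increments, each segmented into an internal limiting membrane (ILM) trace,
a BM trace with a gap at the BM opening, and two rater-marked opening
margins. Depths increase posteriorly, so tissue height is BM depth minus
ILM depth.

Three volumes are computed per eye:

- **ONHV** (optic nerve head volume): the volume between the ILM and a
  continuous BM boundary. Samples where the ILM dips posterior to the BM
  interpolation (the optic cup) are clamped to zero height — they are
  excluded from the sum rather than subtracted.
- **BMDV** (BM displacement volume): the signed volume between BM and a
  per-scan secant line through the BM depths at the two truncation edges.
  Posterior displacement counts positive, anterior (vitread) displacement
  negative, with no clamping; smaller or negative BMDV means more
  flattening of the peripapillary region into the vitreous.
- **CV** (cup volume): the volume between the ILM and the line joining the
  ILM points immediately above the BM opening margins, clamped at zero
  where the ILM is anterior to that line. CV uses the opening geometry only
  and is independent of the BM representation.

## BM representations

Laser penetration through a swollen nerve head degrades the BM image in the
central region, so three representations of BM are supported
(`BMRepresentation`):

- **traditional** — a straight chord joins the BM depths at the rater
  margins, bridging the opening;
- **estimated** — BM inside ±`central_half_width_mm` (default 1.6 mm,
  i.e. a 3.2 mm central region; a configuration knob that should be set to
  the maximum opening extent of the sample under study) is replaced by a
  chord between the segmented BM depths at exactly ±1.6 mm;
- **excluded** — the central region is removed from ONHV/BMDV integration
  altogether.

The secant for BMDV always passes through the outermost *segmented* BM
points of the truncated scan, for every representation, so BMDV differences
between representations isolate the central-region treatment.

A geometric consequence worth knowing: the traditional chord tracks the BM
depth at the margins. When BM bows posteriorly the chord sits anterior to
the true central BM and widening the opening *reduces* ONHV; when BM bows
anteriorly (the high-ICP direction) the chord sits posterior and a wider
opening adds volume. The test suite asserts both directions.

## Discretization

All scans are first truncated symmetrically about their lateral midpoint
(the assumed nerve head center — the scans are taken as concentric) to a
common width, by default the minimum scan width in the set. Each scan then
splits into two half-scans (azimuths θ and θ+180°), yielding 12 half-scans.
Heights are linearly interpolated onto a uniform radial grid of
`n_intervals + 1` nodes from r = 0 to the truncation radius R
(default `n_intervals = 510`). The volume is the sum over the 12 wedges
between adjacent half-scans of per-interval trapezoidal prisms:

    V = sum_w sum_i  base_area(r_i, r_{i+1}) * mean(4 corner heights)

The mean of the four corners is the bilinear-consistent choice; a prism
with any invalid corner is dropped. Two base-area conventions are
implemented because the planar-trapezoid figure and the word "sector" both
appear in descriptions of this construction, and they differ by a
systematic factor:

- `chord` (default): `(r1² − r0²)·sin15°·cos15°`, the planar trapezoid
  between the bounding rays. A flat surface of height h integrates to
  exactly `3hR²` (the inscribed dodecagon).
- `sector`: `(π/12)(r1² − r0²)`, the annular sector; a flat surface gives
  exactly `πhR²`.

Their ratio is `6/(2π) ≈ 0.955` for any radially symmetric surface. Every
reported volume carries its `base_mode`; cross-study comparisons must hold
it fixed.

Numerical notes: resampling is plain linear interpolation; beyond the
outermost retained sample the edge value is held (an error below one sample
spacing). In the excluded representation node validity is the analytic rule
r ≥ central half-width, so exclusion does not depend on how sample spacing
brackets the cutoff; elsewhere a node is valid only when bracketed by valid
samples. Negative ONHV/CV heights are clamped to zero before integration;
BMDV is never clamped.

## Phantom family and oracle

`PhantomParams` defines radially symmetric analytic surfaces: BM is a flat
reference plane at `baseline_z_mm` plus a quadratic bow
`β(1 − (r/R)²)` (β > 0 posterior); the ILM sits above BM by a Gaussian bump
`A·exp(−r²/2σ²)` minus an optional parabolic cup. The BM trace is withheld
for |x| < `opening_radius_mm` with margins at the flanking samples.
Defaults (R = 2.795 mm, 1,024 samples per scan, 3.87 µm axial pixels,
A = 0.5 mm, σ = 0.8 mm, β = 0.1 mm, 1.5 mm opening) describe a mildly
swollen nerve head on a Spectralis-like grid.

Because the phantom is radially symmetric, ground truth is the solid of
revolution `2π∫ r·h(r) dr`, evaluated by dense trapezoid quadrature
(20,001 nodes, ≈ 40× the estimator grid) on the representation-specific
height function, times `3/π` in chord mode. The estimator agrees with this
oracle to well under 1% at 510 intervals for all three volumes, all three
representations and both base modes. `calibrate_bump_amplitude` inverts the
pure-bump oracle (linear in A; bow and cup set to zero) to hit a target
ONHV exactly.

The phantom emulates geometry only: no speckle, no layer-intensity model,
no scan decentration, and segmentation error only as optional additive
Gaussian pixel jitter. Passing oracle tests therefore validates the
integration and representation logic, not robustness to real segmentation
artifact — which is precisely the uncertainty the three BM representations
exist to bracket.

## Cohort generator

`simulate_cohort` draws, per subject, ICP ~ Uniform(10, 55) cm H₂O and one
random intercept per outcome ~ N(0, `sd_subject_mm3`²); both eyes are
usable with probability `p_both_eyes` (defaults 17 subjects, 13/17 — thirty
eyes in expectation). Each eye receives volume = intercept + slope·ICP
(+ `gcc_coef`·GCCV for ONHV) + subject effect + N(0, `sd_eye_mm3`²). The
default intercepts and slopes are the published univariable traditional-
representation estimates (ONHV 4.606 + 0.136·ICP; BMDV 2.100 − 0.038·ICP,
mm³ and cm H₂O); `gcc_coef` defaults to 0 so the univariable law is exact.
Variance components (subject 1.2, eye 0.5 mm³) were fixed once to give
eye-level scatter consistent with one-eye Pearson correlations around 0.7;
between-eye correlation beyond the shared intercept is not modeled. A
single integer seed drives one `numpy` generator; all draws flow from it.

## Association models

`fit_gee` is an identity-link linear GEE with exchangeable working
correlation clustered by subject and robust sandwich standard errors
(statsmodels); Wald 95% CIs and normal p-values per term. Working
independence is available for sensitivity. A perfect linear fit leaves the
exchangeable parameter and the sandwich undefined, so that case short-cuts
to the exact least-squares coefficients with zero SEs (p = 0 for nonzero
terms, 1 at zero); non-finite exchangeable estimates fall back to working
independence. No small-sample CI correction and no multiple-testing
adjustment are applied. `one_eye_regression` takes the right eye unless
only the left is available, fits OLS, and reports the Pearson r;
`pairwise_correlation` gives Pearson rho with a two-sided p.

Simulation sizes used by the checked-in tests: parameter recovery uses 50
replicate cohorts of 500 subjects (mean slope bias under 5% of the
generating value) plus exact recovery on noiseless cohorts; smaller
cohorts (150–400 subjects) exercise clustering and one-eye concordance.

## Known limitations

- The shared nerve-head center is assumed to be each scan's lateral
  midpoint; decentration between scans is not modeled or corrected.
- The estimated representation requires segmented BM at ±1.6 mm; openings
  wider than the central region are an error rather than a fallback.
- The quadrature oracle exists only for radially symmetric phantoms; the
  angular-harmonic hook is for qualitative asymmetry tests.
- Whether the original MATLAB implementation used chord or sector base
  areas is unresolved (≈ 4.5% systematic difference); both are provided
  and results are labeled.
- Published CI/p-value equality is not claimable: the original SPSS GEE
  scale and CI conventions are unspecified, and the clinical coefficients
  depend on 30 real eyes not shipped here.
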