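# Methods

This note records the models the package implements, the defaults it
ships, and the design decisions taken where the problem was genuinely
open. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Synthetic cohort

### What the phantom emulates

A desk-scale pelvis on a 64 × 64 × 48 grid at 4 mm isotropic spacing
(256 × 256 × 192 mm): an elliptical body contour, a sacral bone column
and two femoral-head spheres (rigid throughout the course; their
centres are the registration landmarks), an ellipsoidal PTV with
default volume ≈ 1170 cc (configurable across roughly 876–1532 cc via
`spec_with_ptv_volume`), a spherical bladder (≈ 246 cc), a rectal tube
carved out of the PTV, a whole-bowel (WB) ellipsoid wrapped
anterior/superior of the PTV, and three spherical gas pockets
(radius 18 mm, ≈ 73 cc total) inside WB. Representative HU values:
gas −950, soft tissue ≈ 10–45 by organ, bone 700, exterior −1000, plus
Gaussian HU noise (σ = 12 HU) inside the body. Grid size and every
geometric parameter are fields of `PhantomSpec`.

Pocket centres were chosen (once, by a clearance search against the
rendered organ masks) so that each pocket stays inside WB, clear of
PTV/bladder/rectum/bone, and within the PTV ± 5 mm cranio-caudal band,
with enough margin that a +80% volume expansion remains feasible.

### Fraction anatomies and the ground-truth DVF

A fraction with target gas-volume change ΔV (%) rescales each pocket
radius by (1 + ΔV/100)^(1/3), so the analytic gas volume changes by
exactly ΔV; the voxelized volume tracks it to about ±1 percentage
point at this grid resolution (the package-level contract is ±3
points over requests in [−30%, +80%]). The displacement field of the
rescaling — linear stretch inside the pocket, the volume-preserving
radial push ρ → (ρ³ + r1³ − r0³)^(1/3) outside, smoothstep-tapered to
zero 40 mm beyond the pocket surface — is summed over pockets (plus an
analogous small bladder term) and recorded as the ground-truth DVF
mapping planning points to fraction points. Because the taper dies out
before reaching bone, landmarks never move and a perfect registration
has zero TRE. Pulling fraction labels back through the DVF reproduces
the planning labels except inside a one-voxel interpolation shell at
the pocket surfaces (asserted in the tests).

Bladder volume varies per fraction (Gaussian, σ = 1.8%, resampled
until inside the 5% anatomical-stability cap); the body contour is
held fixed, trivially within its 8% cap. The cohort default is 28
patients × 25 fractions; per-patient mean ΔV_BC ~ Uniform(−5%, +45%)
with per-fraction Gaussian noise (σ = 10%), clipped to [−30%, +80%].
No clinical distribution of ΔV_BC is published, so these ranges are a
design choice: wide enough to create both between-patient (OLS) and
within-patient (fixed-effects) signal, narrow enough to stay
geometrically feasible. They are configuration, not a claim about any
cohort.

### What the generator does *not* emulate

CT texture and scatter/cupping artifacts, peristaltic repositioning of
bowel loops (pockets scale in place), non-gaseous luminal content,
stomach (the exclusion rule is still enforced structurally), body
habitus change, and intra-fraction motion. Consequently, passing tests
demonstrate the correctness and sensitivity of the analysis chain —
not that clinical effect sizes are reproduced; clinical magnitudes
depend on patient images this package does not have.

## HU → RED calibration

Base anchors (HU, RED): (−1000, 0.001), (−200, 0.82), (0, 1.0),
(300, 1.15), (1500, 1.85), linear between — the standard shape of a CT
electron-density calibration; the exact clinical table of any vendor
is not public, so the anchors are configurable. Segment factors
(defaults 0.995 / 0.977 / 0.972 for air / soft tissue / bone) multiply
the base curve within their HU range. Because stepwise factors alone
would create discontinuities at −200 and 300 HU, the factor is
linearly cross-faded over ±25 HU around each breakpoint; with the
default anchors this preserves monotonicity (checked at build time and
exhaustively in tests). Input HU is clamped to [−1000, 1500].

`derive_segment_factors` inverts the construction: given paired
(reference, recalculated, HU) grids, each factor is the mean
reference/recalculated dose *ratio* over in-segment voxels. A ratio —
rather than a mean Gy difference — is used because the factors act
multiplicatively on the curve; the round-trip recovers injected
factors to three decimals.

## Dose engine

A deliberately transparent stand-in for a clinical convolution
algorithm: 12 coplanar equispaced parallel beams; per beam, dose =
aperture × exp(−μ_eff · d_w), where d_w is the water-equivalent depth
(cumulative RED along the beam axis, computed after in-plane rotation
of the volume) and the aperture is the beam's-eye PTV projection
dilated 8 mm and softened by a 5 mm Gaussian penumbra.
μ_eff = 0.005 mm⁻¹ gives a depth-dose falloff of the right order for
6 MV photons. The beam sum is scaled once, on the planning anatomy, so
the median PTV dose equals the 2 Gy/fraction prescription; daily
recalculations reuse that scale (fixed machine output). That choice is
what makes the engine a usable instrument here: gas expansion or
density reduction shortens radiological paths and *must* raise
downstream dose rather than being normalized away. There is no scatter
kernel, no couch, no MLC/fluence optimization, and no claim of
clinical dosimetric accuracy.

`radiological_depth` also exposes a generic point-source ray integral
(uniform sub-voxel stepping at half the minimum spacing) used by the
tests as the slow reference for the depth computation.

## Warping, QA gates, accumulation

Dose is mapped to planning geometry by pull-back (backward) warping:
the value at a planning voxel is the trilinear sample of the fraction
dose at (planning point + DVF displacement). Pull-back is standard and
mass-agnostic; no energy/mass-conserving dose mapping is attempted.
Samples outside the fraction grid contribute 0 Gy and are counted in
the QA ledger.

Each fraction is gated on two criteria: mean landmark TRE ≤ 3 mm
(planning landmarks mapped through the DVF vs fraction landmarks) and
gamma 2%/2 mm pass rate ≥ 90% of the warped dose against the directly
recalculated fraction dose, inside a pelvic ROI (body voxels on axial
slices intersecting the PTV ± 5 mm). In synthetic runs the
"registration" defaults to the generator's ground truth and passes by
construction; `dvf_noise_mm` injects rigid offsets of random direction
and magnitude to exercise the gates. A failing fraction triggers an
optional retry hook (no-op by default, mirroring a re-registration
step whose parameters are site-specific) and is excluded from
accumulation after `max_retries`. Accumulation is voxel-wise summation
of accepted warped fractions on the shared planning geometry.

## Gamma index and TRE

Global gamma: dose difference normalized to the global reference
maximum, low-dose cutoff 10% of that maximum, DTA search on a
displacement lattice of step DTA/5 per axis within radius 3 × DTA,
evaluated dose interpolated trilinearly; out-of-grid lattice samples
are ignored. Published 2%/2 mm analyses rarely state these
completions; all are configurable. The implementation enumerates
lattice displacements in increasing length and stops refining a voxel
when the distance term alone exceeds its current best gamma — exact
with respect to the full lattice search (verified against a
brute-force oracle). For QA gating, a `gamma_cap` (default 1.25 inside
the pipeline) additionally stops refining voxels that are already
known failures; pass/fail is unaffected for any cap ≥ 1, only the
reported gamma values above the cap become upper bounds. Gamma is
directional by definition; the suite pins an asymmetric case. TRE is
the plain Euclidean landmark distance in world mm.

## DVH and endpoints

Cumulative DVHs are built by direct voxel sampling (no sub-voxel
supersampling) with a 0.05 Gy default bin width; at desk-scale grids
the binning error is far below the precision of any reported endpoint,
and a refinement-stability test pins it. Dx%/Dxcc read the curve by
linear interpolation on the cumulative volume axis — D0.03cc is
usually sub-voxel and is therefore an interpolated, not a
nearest-voxel, quantity. V45 interpolates the same curve at 45 Gy.
Cohort summaries report within-patient medians of Δ and δ with
percentile-bootstrap 95% CIs (2000 resamples) and threshold-exceedance
counts (|δ| ≥ 1/2/3% for PTV endpoints, |Δ| ≥ 0.5/1/2/3 Gy for WB
endpoints).

## Association statistics

* Spearman ρ with a BCa (bias-corrected and accelerated) bootstrap CI:
  2000 patient-level resamples, bias correction from the bootstrap CDF
  at the point estimate, acceleration from the jackknife skewness.
  BCa is the strictest reading of a "bias-corrected bootstrap";
  replicates with a constant margin are dropped.
* OLS slope per 10% BC expansion with HC3 covariance and t(n−2)
  critical values. Normal quantiles visibly undercover with cohorts of
  this size; the t-based interval restores near-nominal coverage
  (asserted by a 500-replicate simulation in the acceptance tests).
* Fixed-effects model: dummy-variable OLS with patient intercepts, a
  linear fraction-index covariate and the per-10% slope;
  cluster-robust (CR1) covariance by patient; inference on t with
  G − 1 degrees of freedom (G = number of patients). The estimator is
  algebraically identical to the within (demeaned) estimator, which
  the tests verify to 1e-8.
* BH-FDR: step-up adjustment via statsmodels. The five endpoints form
  one family per test type; whether Spearman and OLS p-values should
  be pooled into a single 10-test family is ambiguous in practice, so
  both modes exist (`pool_fdr_families`), with separate 5 + 5 as the
  default. Fixed-effects p-values are confirmatory and never
  FDR-adjusted.
* `simulate_association_cohort` generates endpoint-level panels with
  known injected slopes (optionally different at the fraction and
  course level) for coverage/recovery studies; all stochastic routines
  take explicit seeds and are reproducible run-to-run.

## NTCP

NTCP(V45) = 1 / (1 + (V50/V45)^k) with V50 = 130 cc, k = 1.1; V45 = 0
returns 0 as the continuous limit, the curve is strictly increasing and
NTCP(V50) = 0.5 exactly. Triage bands classify V45 into <300 cc,
300–500 cc (closed interval — both edges belong to the middle band),
and >500 cc. Planned-vs-accumulated comparison computes NTCP per
patient from each DVH's V45 and summarizes mean ± SD per stratum with
a two-sided paired t-test; strata with fewer than two patients, or
with exactly zero-variance paired differences, are reported with the
difference and a "degenerate test" note instead of a fabricated
p-value. Model parameters are fixed inputs; fitting V50/k, other NTCP
families, and late-toxicity modelling are out of scope.

## Pipeline defaults and problem sizes

`run_course` executes the full chain per patient: planning dose (fixes
the output scale), then per fraction anatomy → RED → dose → warp → QA
→ BC segmentation, then accumulation, endpoint tables, association
table and NTCP table, all as CSV plus a JSON manifest. The full
default cohort (28 × 25 at 64 × 64 × 48) runs in minutes on one core;
the test suite exercises the identical code paths on reduced cohorts
(1–3 patients, 1–25 fractions) chosen so the whole suite stays fast,
and the acceptance checks use a 500-replicate endpoint-level
simulation at 8-patient scale for statistical coverage rather than
repeated voxel-pipeline runs. Whole-bowel V45 is only meaningful at
the full 25-fraction prescription (50 Gy course); runs with fewer
fractions report V45 of the proportionally lower course dose, which is
0 below 23 fractions.

## Known limitations

The dose engine is a first-order attenuation model: effect sizes in Gy
per 10% expansion on phantoms are of the order of a few hundredths of
a Gy, smaller than clinically reported tenths of a Gy, because there
is no scatter, no fluence modulation and the phantom's gas pockets are
modest relative to a real bowel. The registration is ground truth, so
QA gates exercise the gating logic, not a registration algorithm.
Toxicity grades on synthetic cohorts are band-derived labels, not
clinical outcomes. None of the statistical machinery depends on these
simplifications, which is the point of the design: the chain is
validated on constructions whose truth is known exactly.
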