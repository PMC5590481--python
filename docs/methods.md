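# Methods

This note documents the models, numerical choices and limitations behind
`rhvort`, in the order data flows through the pipeline.

## Data model and units

Velocity fields live on regular, possibly anisotropic voxel grids
(`GridSpec`): voxel indices are 0-based, axis order (x, y, z), world
coordinates in mm at voxel centers, time in ms with timestep k at k·dt.
Velocities are stored in cm/s (the native phase-contrast unit), and every
numeric kernel converts to SI internally. Defaults reflect typical 4D Flow
acquisitions: ~2×2×3 mm voxels, dt = 50 ms, venc 100–150 cm/s. Integrated
vorticity is reported in mm³/s (|ω| in s⁻¹ × voxel volume in mm³); the
clinical literature for this metric is not consistent about absolute
units, so the package keeps one explicit unit and treats published cohort
summaries as internally consistent numbers on their own scale.

## Noise masking

Velocity is zeroed wherever the co-registered magnitude image is **at or
below** a threshold — inclusive, so an intensity exactly at the threshold
is removed. The threshold is given either absolutely (scanner units) or
as a fraction of the maximum intensity; the default, 3 % of max,
reproduces the common absolute setting of ~14 on images peaking near 470
without hard-coding a scanner's intensity scale. The operation is
idempotent and never touches voxels above threshold. Masked voxels are
excluded from the unwrapping step's consistency graph (they are noise;
letting them anchor corrections would be wrong), which fixes the pipeline
order as mask → unwrap.

## Anti-aliasing (velocity unwrapping)

True speeds beyond ±venc alias into [−venc, venc) by multiples of 2·venc.
Two mechanisms are provided:

* `detect_aliased` is the local diagnostic: flag a voxel when its value is
  more than venc from the median of its (up to six) face neighbours, with
  wrap count k = round((median − v)/(2·venc)). This is reliable for
  isolated aliased voxels and region rims, and reduces to classic 1-D
  jump detection along a scan line. It is *not* sufficient as a
  corrector: the interior of a large aliased region is locally
  self-consistent (wrapping is locally a constant −2·venc shift), so a
  simultaneous detect-and-correct sweep sees only the rim, and — as
  direct experiment during development showed — corrected rim voxels and
  still-wrapped interior voxels then re-flag each other in a stable
  cycle that never converges.
* `unwrap` therefore works region-wise. Each iteration partitions the
  volume into connected components of mutual consistency (face neighbours
  differing by ≤ venc), takes the largest component as the anchor, and
  rigidly shifts every component adjacent to the anchor by the integer
  multiple of 2·venc given by the rounded median of its boundary
  differences to the anchor. Aliased islands merge into the anchor one
  adjacency layer per iteration, so nested (multiply-wrapped) regions
  resolve in as many iterations as their nesting depth; the iteration cap
  is 10, and heavily aliased inputs typically finish in ≤ 5. This is the
  standard region-merging approach to phase unwrapping, applied per
  velocity component and timestep.

Corrections are exact floating-point multiples of 2·venc, and the
synthetic wrap operator is implemented as v − 2·venc·⌊(v+venc)/(2·venc)⌋
so that the subtraction is exact for values within a few binades of venc;
together these make the wrap → unwrap round trip bit-exact on smooth
fields (peak ≤ 3·venc, neighbour differences < venc). The report records
per-iteration correction counts; `converged` is true iff the final
iteration corrected nothing. Pathological inputs (e.g. a ±venc
checkerboard) have no self-consistent assignment; they terminate at the
cap with `converged=False` rather than raising.

## Vorticity and ROI integration

ω = ∇×v is evaluated with second-order central differences at interior
voxels and first-order one-sided differences at grid boundaries,
honouring anisotropic spacing. On linear fields (solid-body rotation)
central differences are exact, which provides a machine-precision oracle
(ω = 2Ω); on a Lamb–Oseen tube whose core spans 4 voxels the
volume-integrated |ω| matches the circulation Γ·L within 0.5 %.

Thresholding zeroes vectors with |ω| **strictly below** τ (ties survive).
ROI membership is by voxel-center inclusion in an oriented box with
half-open faces, which makes splitting a box along a plane an exact
partition of its voxel set — `roi_from_landmarks` uses this to cut the RH
box into RA and RV at the tricuspid plane (the plane must cross the box
and must not be parallel to the long axis). Integration is the masked sum
of |ω| times the voxel volume; only nonzero members are summed so that
the floating-point summation order does not depend on how much zeroed
buffer the box includes — moving a face by one voxel inside the buffer
then changes the integral by *exactly* zero, which is the point of
thresholding before integrating: the metric becomes insensitive to the
subjective placement of the box.

Scaling schemes: `NONE` (constant τ, raw integral), `SS` (integral / CI),
`TS` (τ = τ_ref·CI/CI_ref, raw integral), `SS_TS` (both). Defaults
τ_ref = 0.04 s⁻¹ (the reference study's compromise between data loss and
interobserver agreement) and CI_ref = 2.4 L/min/m² (control-group mean).
The reference subject behind τ_ref is not identifiable from published
material, so both are explicit configuration. `SS` *divides* by CI — the
only direction that removes a proportional dependence of total vorticity
on cardiac output.

## Event timing

Through-plane flowrate is the disk integral of v·n̂, computed by trilinear
interpolation at the points of a uniform in-plane grid restricted to
r ≤ R, each weighted by the grid spacing squared (default spacing:
min(voxel edge)/4; at R/20 the uniform-profile error is < 0.1 %). The
in-plane basis is derived from a sign-canonicalized normal so that
flipping the probe normal negates the flowrate exactly. The disk is fixed
in space — no valve tracking — so the series is trusted only near the
timestep the disk was placed for, which suffices because only the peak-E
timestep is consumed.

Direct detection: t_E is the largest *distinct* local maximum of Q(t) in
the diastolic window (default: second half of the cycle; configurable via
`systole_end_hint_ms`), t_A the last distinct local maximum after it.
"Distinct" means prominence ≥ 5 % of the series range — an operational
stand-in for visual peak judgement. Earliest sample wins ties; a window
whose largest value sits at the final sample is flagged as possibly
truncated (prospective gating cuts late diastole). No distinct peak →
an `EWaveAmbiguousError` the caller can catch.

Hybrid detection (A-dominant filling): the E-to-A interval Δt is measured
between the two distinct positive diastolic peaks of the LV dV/dt curve —
with quadratic sub-sample peak refinement, justified because the
cine-derived LV curve is smooth and better sampled than the 4D Flow data —
and t_E = t_A(RV) − Δt, snapped to the flowrate sampling grid. A constant
gating offset (default 0 ms, settable to ~80 ms where prospective 4D Flow
is combined with retrospective cine) is added to LV times explicitly,
never silently; it cancels inside Δt. dV/dt uses central differences with
first-order forward/backward differences at the endpoints and requires
uniform sampling.

The pipeline accepts the direct estimate only when a distinct later
A-peak confirms the E-before-A pattern; otherwise (ambiguous, or largest
peak last) it falls back to the hybrid method when an LV volume curve is
available. Direct detection alone cannot tell a dominant A-peak from a
dominant E-peak.

## Cohort statistics

Lin's concordance ρ_c = 2·cov(x,y)/(var x + var y + (mean x − mean y)²)
uses population (1/n) moments per its original definition; degenerate
constant inputs return 1 (equal) or 0 (unequal). The interobserver sweep
covers τ = 0.005 to 0.100 s⁻¹ in 0.005 steps.

Group comparisons use Welch's unequal-variance t-test, two-sided, with
sample (1/(n−1)) SDs and Welch–Satterthwaite degrees of freedom. The
choice is evidence-based: the reference cohort's published p-values are
reproduced to all three printed decimals by Welch's test from its printed
group summaries (0.011, 0.015, 0.024, 0.025, 0.048 for the
well-conditioned columns), while the pooled-variance test gives ≈0.009
for the first column; the one published 0.012 reproduces as 0.0114,
consistent with rounding of the printed means/SDs. Raw p-values are
reported across the grid, matching the usual presentation; Bonferroni
columns are available behind a flag. Analytic power uses the noncentral
t distribution at the Welch df.

## Synthetic data

Generators sample analytic expressions at voxel centers — no
partial-volume modelling — so every oracle stays closed-form. Randomness
always flows through an explicit seed; a single seeded generator per
call gives bit-reproducible outputs.

* Analytic flows: uniform, solid-body rotation, Lamb–Oseen tube, Hill's
  spherical vortex (lab frame: co-moving interior solution + exterior
  dipole, continuous at the sphere), Poiseuille tube.
* Smooth blob fields for unwrapping tests: sums of roughly isotropic
  Gaussian blobs (σ ≈ 3–5 voxels, centers kept off the boundary),
  normalised to a chosen multiple of venc. This emulates how aliasing
  arises in practice — localized jets exceeding venc inside a smooth
  surrounding field — and such compact wrapped regions are the case the
  region-merging unwrapper (and any unwrapper) can resolve; wrapped
  regions touching the image boundary or shaped like thin open sheets
  are genuinely harder and are not claimed.
* Cardiac phantom: a cylinder-confined jet through the valve disk with a
  plug-plus-cosine-taper radial profile whose plane integral is analytic,
  so the true through-valve flowrate equals the prescribed lobe sum
  Q(t) = Q_sys·g(t; t_sys) + Q_E·g(t; t_E) + Q_A·g(t; t_A) (Gaussian
  lobes, default width 60 ms) exactly at every timestep. The LV volume
  curve integrates the same lobes (ejection negative) delayed by
  `lv_delay_ms` (default 30 ms, emulating the 20–50 ms left/right offset
  of combined cine + 4D Flow exams) and is sampled at 25 ms, the typical
  advantage of retrospective cine over 4D Flow; negative volumes are
  rejected. Event-time defaults (t_sys 150, t_E 400, t_A 750 ms in a
  1000 ms cycle) and peak flowrates (E-dominant 300/150 mL/s,
  A-dominant ~110/280 mL/s) are chosen as physiologically typical; the
  published material gives no quantitative right-heart flow magnitudes
  to calibrate against, so phantom amplitudes are free parameters, not a
  fit to the cohort.
* Cohort simulation: integrated-vorticity draws per group from Gaussians
  truncated at zero (negatives resampled — the metric cannot be
  negative and the reference SDs are large relative to the means), with
  defaults at the reference study's strongest combination: 14 controls
  709 ± 325 vs 20 RVDD 408 ± 303. Truncation shifts the true sampling
  moments (RVDD mean 408 → ≈462), so analytic checks against the
  simulation use truncated-normal moments, under which the Welch
  rejection rate at n = 14/20 is ≈0.69 and matches the Monte-Carlo rate
  within 1 %.

What passing on phantoms does *not* show: real 4D Flow data has spatially
correlated noise, moving valve planes, partial-volume and segmentation
errors, heart-rate drift between acquisitions, and chamber geometry far
from a cylinder-confined jet. The phantoms validate the numerics and the
logic of the methods, not their clinical accuracy.

## Problem sizes and numerical tolerances

Tests and the acceptance script run on desk-scale grids chosen so each
check exercises its resolution requirement and no more: 32³ for the curl
oracle (exact for linear fields; tolerance 1e−6 relative), 40×40×16 with
a 4-voxel core for circulation (1 %), 24³ × 100 seeds for unwrapping
(bit-exact), 48² in-plane for the Poiseuille disk (2 % at spacing R/20),
32×32×24×20 phantoms × 100 seeds per regime for timing (within one 50 ms
timestep), 1000 seeded cohorts for the power comparison (±3 %). File
round trips are lossless at float32 for volumes and full-decimal text
for CSV.

## Known limitations

No eddy-current/background-phase correction, no Laplacian or graph-cut
unwrapping, no valve tracking or automatic disk/ROI placement from
images, no chamber segmentation, no Q-criterion/λ₂/Lagrangian coherent
structure analysis, no DICOM ingestion. The RA/RV split requires the
tricuspid plane to be (near) perpendicular to the long axis, as an
oriented-box representation cannot express an oblique cut.
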