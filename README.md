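# rhvort

Right-heart vorticity analysis for 4D Flow phase-contrast cardiac MRI.

Right ventricular diastolic dysfunction (RVDD) — impaired relaxation and
stiffening of the right ventricle, typically downstream of pulmonary
arterial hypertension — alters the coherent flow structures that form in
the right atrium (RA) and right ventricle (RV) during diastolic filling.
`rhvort` implements a quantitative pipeline for probing this: it takes
time-resolved three-component velocity fields v(x, t) (one 4-D NIfTI per
component plus a JSON sidecar), cleans them, and reduces them to a scalar
metric per subject — spatially integrated vorticity magnitude at peak
early diastole,

```
V(τ) = Σ_{voxels in ROI, |ω| ≥ τ} |ω|  ×  v_voxel ,    ω = ∇ × v ,
```

evaluated inside an oriented rectangular-prism ROI around the RA, RV, or
combined right heart (RH), with the threshold τ and/or the integral scaled
by the subject's cardiac index CI (schemes `NONE`, `SS` = integral / CI,
`TS` = τ·CI/CI_ref, `SS_TS` = both). Cohorts are then compared with Welch
t-tests per (ROI, scheme, τ) combination, and interobserver agreement is
quantified with Lin's concordance coefficient swept over τ.

The stages, each exposed as library functions:

* **preprocess** — velocity zeroed where the anatomical magnitude image is
  at or below a noise threshold (≈3 % of maximum intensity); velocity
  aliasing (wrapping by 2·venc) corrected by an iterative region-merging
  unwrapper capped at 10 iterations, with corrections that are exact
  multiples of 2·venc.
* **vorticity** — ∇×v by central differences on the anisotropic voxel
  grid, thresholding, oriented-box integration, CI scaling schemes.
* **timing** — through-plane flowrate Q(t) through a disk probe at the
  tricuspid valve (trilinear interpolation on an in-plane quadrature
  grid); E-wave time read directly from the flowrate peak in normal
  filling, or — when the A-wave dominates — by measuring the E-to-A
  interval on the left-ventricular dV/dt curve and backing off from the
  A-peak (the hybrid method).
* **stats** — Lin concordance ρ_c and its threshold sweep
  (0.005–0.100 s⁻¹), Welch t-tests from raw values or group summaries,
  analytic Welch power.
* **synthetic** — analytic fields (solid-body rotation, Lamb–Oseen tube,
  Hill vortex, Poiseuille tube), a cardiac phantom with a biphasic
  diastolic jet whose through-valve flowrate is known in closed form, and
  cohort simulation at the reference study's effect size. Every
  downstream stage is testable against these closed-form truths.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/01_anti_aliasing.py` prints

```
peak speed              : 150.0 cm/s (venc = 100)
aliased samples         : 305
iterations run          : 2 (cap 10)
corrected per iteration : [305, 0]
converged               : True
recovered bit-exactly   : True
```

— a smooth field whose 150 cm/s jet exceeds the 100 cm/s encoding limit
is wrapped the way a scanner would record it, and the unwrapper recovers
the original field exactly, because every correction it applies is an
exact floating-point multiple of 2·venc. Similarly,
`python examples/04_cohort_statistics.py` recomputes the reference
cohort's strongest group separation from its published summaries:

```
reference cohort, RA/SS/tau=0.04:
  control 709 +/- 325 (n=14), RVDD 408 +/- 303 (n=20)
  Welch t = 2.73, df = 26.8, p = 0.011 (published: 0.011)
```

i.e. controls carry significantly more CI-normalised early-diastolic RA
vorticity than RVDD subjects at a 0.04 s⁻¹ threshold.

A thin CLI mirrors the stages for shell use:
`rhvort simulate | preprocess | vorticity | timing | cohort | sweep`
(see `rhvort --help`).

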