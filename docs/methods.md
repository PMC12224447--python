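# Methods

## Measurement model

A dual-echo (spin- and gradient-echo) dynamic acquisition samples both
echoes of every voxel at each repetition time.  The generative model
used throughout — by the simulator forwards and the analysis backwards —
is

    S(t) = S0 * exp(-TE * dR(t)) + noise,

with `S0` the mean signal over the pre-bolus baseline window and `dR(t)`
the transverse relaxation-rate change caused by the contrast agent.
Default timing follows a 3 T SAGE-EPI bolus protocol: TR = 1.5 s,
TE = 22 ms (gradient echo) and 90 ms (spin echo), 10 baseline frames and
60 frames in total (15 s baseline + 75 s bolus window).

The first-pass bolus is modelled as a gamma-variate,

    C(t) = A * (t - t0)^alpha * exp(-(t - t0)/beta)   for t > t0,

whose maximum lies at `ttp = t0 + alpha*beta`.  Ground-truth voxels are
parameterized by peak amplitude, continuous time-to-peak and shape
`(alpha, beta)` per echo; the arrival time follows from the ttp
identity, which avoids a redundant degree of freedom.

Gradient-echo curves may carry a contrast-extravasation component.  The
two-parameter reference-curve model is used both ways: the simulator
writes `dR_meas = K1*ideal - K2*cumint(reference)` and the correction
estimates (K1, K2) by ordinary least squares of the measured curve
against the reference and its running integral, then adds the K2 term
back.  With a noiseless voxel whose shape matches the reference the
planted coefficients are recovered to machine precision; this exactness
is what makes the correction testable by round-trip.

## Loop geometry

The vascular hysteresis loop is sampled from the *fitted* curves (not
the raw, noisy ones) on a dense common grid at four times the
acquisition rate, with the spin-echo change on the x-axis and the
gradient-echo change on the y-axis, and closed through the origin (both
gamma-variates are zero before arrival and decay to zero after
washout).  Conventions, each of which is pinned by a unit test:

- **Orientation** is the negated sign of the shoelace area: clockwise
  traversal is +1, counterclockwise −1.  A spin echo that peaks before
  the gradient echo produces a counterclockwise loop, so
  capillary/venule-dominated tissue carries orientation −1 — and the
  sign test asserting that orientation, VTI, I and VIPS flip together
  when the echo order reverses gates every other signed quantity in the
  package.  Loops with |area| below 1e−12 (1/s)² are degenerate:
  orientation 0 and signed parameters 0.
- **VTI** is the orientation-signed shoelace area.
- **I** splits the loop at the point farthest from the origin (robust
  when the two echo peaks differ), resamples the ascending and
  descending branches at common x values, and reports the
  orientation-signed maximum *vertical* separation.  Vertical distance
  at matched x was chosen over point-to-curve Euclidean distance
  because it is reproducible across samplings; the branch-split rule
  and distance definition are the package's own, as no canonical
  definition exists.
- **BVF/CBI/CGI** come from a principal-component decomposition of the
  loop point cloud: axis lengths are projection ranges (max − min, i.e.
  literal axis lengths rather than eigenvalue multiples) and CGI is the
  slope of the first principal direction.  PCA treats x and y
  symmetrically, which a y-on-x regression slope would not.
- **VIPS** is the difference of fitted times-to-peak, ttp_SE − ttp_GE.
  Because ttp is continuous, sub-sample shifts (0.4 s at 1.5 s
  sampling) are resolved to better than 0.01 s on noiseless input.

## Perfusion estimators

Vessel size index and microvessel density are computed from the fitted
peak values (less noise-biased than raw maxima):

    VSI = 0.425 * sqrt(ADC / (gamma * dchi * B0)) * (dR2*/dR2)^(3/2)
    Q   = dR2 / (dR2*)^(2/3)

Defaults: gyromagnetic ratio 2.675e8 rad/(s·T), field strength 3 T,
susceptibility difference 1.15e−7 (SI) at peak contrast concentration,
scalar ADC 0.8e−3 mm²/s (a per-voxel ADC map may be supplied).  All are
configurable and recorded in output sidecars.  Q is computed in
s^(−1/3); the reporting convention multiplies by 10 to express it in
10²·ms^(−1/3), the unit used in clinical tables, where healthy-tissue
values land at ≈ 3–6.

rCBV is the trapezoidal integral of the leakage-corrected ΔR₂\* curve
over the post-baseline window, normalized by the healthy-hemisphere
brain-mean integral, so the healthy-hemisphere mean is exactly 1 before
any report scaling.  This estimator uses the gradient-echo curve of the
dual-echo acquisition itself rather than requiring a separate
single-echo perfusion series; an external series can be substituted.

Maps are NaN outside the brain mask and wherever either echo's fit was
invalid (missing values propagate; no parameter is ever emitted for a
voxel with a failed fit), and the entire lesioned hemisphere is set to
zero, with the midline defined by the grid-column plane (the mask
affine places x = 0 there).

## Gamma-variate fitting

Fits run on the post-baseline window.  Candidate arrival times are
scanned around the first 10%-of-peak crossing; for each, the remaining
parameters have a weighted log-linear closed form (weights equal to the
curve value, approximating the unweighted nonlinear objective), and the
seed with the lowest residual starts a bounded trust-region refinement
with an analytic Jacobian.  Further starts run only if the converged
cost stays above the noise floor estimated from the baseline variance.
Quality gates: a voxel must show a positive excursion above 3 baseline
standard deviations, and converged fits with r² < 0.6 are flagged
invalid (never an exception).  Both thresholds are configurable;
essentially all noiseless synthetic voxels pass at the defaults.  At
peak SNR 20 the fitted time-to-peak is estimator-efficient: its
standard error matches the Cramér–Rao bound (~0.19 s for the default
shape) — a bound worth keeping in mind when interpreting VIPS at low
SNR.

Leakage correction is applied to gradient-echo curves before fitting,
with the whole-brain (healthy hemisphere) mean ΔR₂\* curve as
reference.  Spin-echo curves are fitted without leakage correction: the
reference-curve model is defined for the gradient echo, and spin-echo
extravasation effects are much weaker.  Both the fit window and the
SE-correction choice are exposed in configuration for sensitivity
analysis.

## The synthetic cohort

The simulator is the package's stand-in for the clinical study
population and defines the conditions under which the pipeline is
validated:

- **Phantom**: 24×24×6 grid (configurable up to full acquisition
  matrices), eight volumes of interest mirrored about the midline
  (cortical grey matter, white matter, caudate nucleus, putamen,
  globus pallidus, thalamus, insula, hippocampus), one-voxel background
  rim, and a lesion-side flag per subject (even left/right split).  The
  lesion itself is not modelled — only healthy hemispheres are
  analyzed.
- **Regional truths**: per-region amplitude pairs chosen so peak ΔR₂\*
  spans ~14–30 1/s and ΔR₂ ~3–5 1/s, putting Q in the physiological
  3–6 (10²·ms^(−1/3)) band and VSI at 10–35 µm; most regions have the
  spin echo leading (negative VIPS ≈ −0.5…0 s), the globus pallidus
  the reverse, mirroring the qualitative pattern of healthy tissue.
- **Demographics**: 42 women / 30 men; ages truncated-normal
  (mean 37.6, SD 12, range 20–70); BMI normal per sex (women
  24.8 ± 4.2, men 26.3 ± 3.2 kg/m²) with a positive BMI–age slope in
  men only (r ≈ 0.5), which is exactly the confound the BMI-controlled
  partial correlations exist to remove.
- **Between-subject variability**: a common amplitude factor (SD 8%,
  both echoes — a blood-volume-like effect), an independent
  gradient-echo-only factor (SD 12%) that moves the large-to-small
  vessel ratio, and a shared time-to-peak jitter (SD 0.08 s).  Additive
  Gaussian noise on the magnitude signal (default SD 5 at baseline
  S0 = 1000/800) gives single-voxel peak SNRs of ~40–60; Rician noise
  is deliberately not modelled — at these SNRs the Gaussian
  approximation is excellent and it keeps the round-trip oracle exact.
  This is a known limitation for low-SNR regimes.
- **Planted effects**: linear relative slopes per decade of age on any
  truth field, restricted by region and sex.  The default recovery
  study raises the gradient-echo amplitude by 8%/decade in women only,
  which induces a true female VSI–age partial correlation of ≈ 0.6–0.7
  after pipeline recovery.  The magnitude was fixed once, at the upper
  range of reported aging effect sizes, so that the recovery study is
  well powered (> 95% detection at n = 42) and failures indicate
  pipeline defects rather than sampling noise.
- **Leakage**: fully supported per voxel, but the cohort default is
  K₂ = 0 — the emulated population has intact blood–brain barriers in
  the analyzed (healthy) hemispheres, where extravasation is
  negligible.  Tumor-like leakage can be enabled per region.

What passing tests on this generator do **not** show: robustness to
motion, coregistration error, partial-volume mixing at region
boundaries, arterial input variability, bolus dispersion or recirculation,
field inhomogeneity, or Rician noise floors — none of which are
simulated.

## Analysis granularities and problem sizes

`run_subject` fits every healthy-hemisphere voxel independently and
produces the nine whole-volume maps.  `run_subject_regional` averages
the raw signals within each VOI first and fits one curve pair per
region — the standard region-of-interest practice for dynamic contrast
studies, and an SNR gain of sqrt(n_voxels).  Cohort-level statistics
operate on VOI means either way; the package uses the regional path for
replicate studies (50 cohorts of 72 subjects run in a few minutes) and
the voxelwise path wherever per-voxel maps are the object of interest.
rCBV normalization in regional mode uses the voxel-count-weighted mean
of the VOI integrals, the regional analogue of the whole-brain mean.

## Statistical battery

Per (parameter, VOI) column across subjects: ROUT outlier screening
(robust location by iteratively reweighted least squares with
Lorentzian weights; robust SD from the 68.27th percentile of absolute
residuals with the n/(n−K) small-sample correction; two-sided t
p-values screened by a Benjamini–Hochberg-style step-up at Q = 1%, at
most 30% of a column flaggable; columns under n = 10 are not screened).
Flagged rows are excluded from tests but retained with flags.

The D'Agostino–Pearson omnibus test (K² = Z²(skew) + Z²(kurtosis)
against χ²(2)) gates each comparison: Gaussian columns get unpaired
t tests and Pearson correlations, non-Gaussian ones Mann–Whitney
(exact for group sizes ≤ 20 without ties, tie-corrected normal
approximation otherwise) and Spearman.  Samples under n = 8 are routed
to the non-parametric path with a warning.  Partial correlations use
the first-order closed form on raw values (Pearson path) or ranks
(Spearman path — the non-parametric variant is the package's choice,
as no canonical definition exists), with significance from t at n − 3
degrees of freedom.

FDR adjustment (Benjamini–Hochberg step-up, Q = 5%) is applied within
each parameter's family of group comparisons across the 8 VOIs,
matching how clinical tables present adjusted sex comparisons;
age correlations are reported unadjusted by default (configurable),
reflecting common practice of marking raw p < 0.05 in correlation
tables.  All tests are two-sided at α = 0.05.

## Numerical choices and degenerate inputs

- Non-positive signal frames invalidate a voxel rather than being
  clipped or interpolated — favoring auditability over yield.
- Baseline estimation requires ≥ 3 frames; S0 ≤ 0 invalidates.
- Degenerate loops (identical echo curves) give orientation 0 and zero
  signed parameters; collinear point clouds give CBI = 0; fewer than
  3 points is an error.
- An all-zero leakage reference is an error; leakage fit residual
  variance is reported.
- In `bh_fdr`, NaN p-values pass through unrejected; out-of-range
  p-values raise.
- All randomness flows through numpy Generators seeded from a single
  cohort seed; identical specifications are bit-reproducible.

## Known limitations

Gaussian (not Rician) noise; no arterial input function deconvolution,
so no CBF/MTT; no motion or registration modelling (assumed handled
upstream); rCBV from the dual-echo gradient-echo curve rather than a
separate perfusion sequence; the partial-correlation small-sample
behavior is exact only under bivariate normality of the residuals; and
the simulator's within-region homogeneity (5% amplitude jitter) is far
tidier than real tissue.
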