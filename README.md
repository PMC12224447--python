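# vamkit

Vascular architecture mapping (VAM) from dual-echo dynamic susceptibility
contrast MRI, as a tested, reusable Python package with a synthetic-data
generator in place of patient scans.

## The problem

During a gadolinium bolus, the transverse relaxation rates measured by a
combined spin- and gradient-echo (SAGE) EPI sequence respond differently
to the microvasculature inside each voxel: the spin-echo change ΔR₂ is
dominated by capillaries (diameters below ~10 µm), the gradient-echo
change ΔR₂\* by larger vessels.  Plotting ΔR₂\*(t) against ΔR₂(t) over
the bolus passage traces a closed, time-parametrized **vascular
hysteresis loop** (vessel vortex curve) whose geometry encodes vascular
architecture.  `vamkit` implements the full chain:

1. **Relaxometry** — ΔR(t) = −(1/TE)·ln(S(t)/S₀) per echo, with S₀ the
   mean pre-bolus baseline; reference-curve leakage correction
   (measured ≈ K₁·ref − K₂·∫ref) for the gradient echo; gamma-variate
   fitting C(t) = A·(t−t₀)^α·e^(−(t−t₀)/β) with continuous
   time-to-peak ttp = t₀ + α·β.
2. **Loop geometry** — orientation (+1 clockwise / −1 counterclockwise),
   signed area **VTI**, signed maximum branch separation **I**,
   long-axis slope **CGI**, long-axis length **BVF**, short-axis length
   **CBI**, and the fitted peak-time shift **VIPS** = ttp_SE − ttp_GE.
3. **Perfusion estimators** — vessel size index
   VSI = 0.425·(ADC/(γ·Δχ·B₀))^½·(ΔR₂\*/ΔR₂)^{3/2} (µm), microvessel
   density Q = ΔR₂/(ΔR₂\*)^{2/3} (s^(−1/3)), and rCBV as the normalized
   integral of the leakage-corrected ΔR₂\* curve — nine parameter maps
   per subject, with the lesioned hemisphere zeroed.
4. **Cohort statistics** — per-VOI means joined to demographics, ROUT
   outlier screening (Q = 1%), D'Agostino–Pearson normality gating into
   t/Mann–Whitney and Pearson/Spearman paths, BMI-controlled partial
   correlations with age, and Benjamini–Hochberg FDR (Q = 5%).

Because no clinical data are deposited, the package ships a forward
simulator (`vamkit.simulate`) that generates dual-echo cohorts with
known ground truth — including planted sex-specific aging effects — so
every stage can be validated by recovery.

## Worked example

```sh
python examples/02_vortex_loop_parameters.py
```

```
orientation : -1   (-1 = counterclockwise, SE leads)
I    =   -2.172 1/s    (signed max branch separation)
VTI  =   -6.610 1/s^2  (signed loop area)
VIPS =   -0.400 s      (ttp_SE - ttp_GE)
CGI  =    5.011        (long-axis slope dR2*/dR2)
BVF  =   20.393 1/s    (long-axis length)
CBI  =    0.434 1/s    (short-axis length)
VSI  =    13.99 um     Q = 5.43 x10^2 ms^-1/3
```

The voxel's spin echo peaks 0.4 s before its gradient echo, so the loop
runs counterclockwise and the three signed parameters (I, VTI, VIPS) are
simultaneously negative — the signature of capillary/venule-dominated
tissue.  Note that VIPS resolves the 0.4 s shift exactly even though the
series is sampled every 1.5 s, because it is computed from the fitted,
continuous times-to-peak.  `examples/03_subject_parameter_maps.py` runs
the voxelwise pipeline on a phantom subject and
`examples/04_cohort_statistics.py` analyzes a full 72-subject synthetic
cohort with a planted female-only caliber-aging effect.

A thin CLI wraps the same library calls:

```sh
vamkit simulate --config cohort.yaml --out data/ --seed 1
vamkit maps --subject data/sub-000
vamkit all --out run/ --seed 1
```

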