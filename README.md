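# dceauc

Model-free pharmacokinetic analysis of collagen-targeted dynamic
contrast-enhanced (DCE) MRI, with a digital-phantom simulator for
end-to-end validation.

## The problem

Pancreatic ductal adenocarcinoma is strongly desmoplastic: the tumour
stroma accumulates type I collagen, which both stiffens the tissue and
impairs its perfusion. A small gadolinium-peptide probe that binds type I
collagen (Kd = 1.8 µM, relaxivity r₁ = 16.2 mM⁻¹s⁻¹ for the tri-Gd
molecule, 5.4 per Gd ion) enhances T1-weighted MRI wherever collagen
retains it, while its non-binding stereoisomer washes out with the plasma
(blood half-life ≈ 19 min in mice). Because fibrotic tissue is also poorly
perfused, *early* enhancement reflects probe delivery, not binding — a
model-free readout is needed that cancels the delivery phase.

This package implements that readout and the statistics around it, for
imaging scientists analysing dynamic series (one baseline plus
post-injection volumes at ≈ 5, 20, 35, 45 and 55 min):

- **Normalization and enhancement.** Each time point is scaled so the mean
  dorsal-muscle signal is 1, then per-voxel signal enhancement is
  SE(t) = S(t)/S(0) against the pre-injection baseline.
- **AUC₅₋₅₅** (the core biomarker): the trapezoidal area of
  SE(t) − SE(5 min) over the 5–55 min window, per voxel, then averaged over
  the whole tissue ROI. Using the 5-min point as reference makes the area
  *signed*: positive for retention (collagen binding), negative for
  washout, and largely independent of how much probe was delivered.
- **AUC₀₋₅₅**: the conventional area of SE − 1 from injection, which is
  perfusion-dominated — the contrast between the two is the point.
- **Enh5 and PerfVF**: enhancement at 5 min, and the fraction of ROI voxels
  whose Enh5 strictly exceeds the pooled-cohort median (the "well-perfused
  volume fraction").
- **Cohort statistics**: mean ± SEM, unpaired two-tailed equal-variance
  t-tests, Pearson correlations of each biomarker against tissue
  hydroxyproline (the wet-assay surrogate for total collagen), box-plot
  summaries.
- **SHG coregistration**: second-harmonic-generation collagen micrographs
  are max-projected, block-averaged from 9.18 µm to MR resolution (250 µm),
  rigidly registered to an ex-vivo MR slice by normalized cross-correlation,
  and compared by Dice and directional overlap fractions.

Because no in-vivo dataset is bundled, the `phantom` module simulates the
whole acquisition — monoexponential plasma input, two-compartment tissue
exchange with reversible second-order collagen binding, spoiled
gradient-echo readout (TR 92.6 ms, flip 35°), Rician noise — over
parametric tumour/pancreas/muscle phantoms with heterogeneous collagen
(tumour ≈ 1224 µg/g hydroxyproline vs pancreas ≈ 523 µg/g, with
low-collagen necrotic cores) and emits voxel-level ground truth.
See `docs/methods.md` for the model and every default.

## Worked example

```python
import numpy as np
from dceauc.pipeline import simulate_cohort, analyze_cohort, assays_from_truth
from dceauc.stats import cohort_report

studies = simulate_cohort(seed=1)                      # 8 targeted + 7 control + 3 sham
summaries, threshold, curves = analyze_cohort(studies)
report = cohort_report(summaries, assays_from_truth(studies))

print(summaries.groupby(["tissue", "probe"])[["auc_5_55", "auc_0_55", "enh5", "perf_vf"]]
      .mean().round(2))
```

```
                   auc_5_55  auc_0_55  enh5  perf_vf
tissue   probe
pancreas targeted    -11.34     20.62  1.61     1.00
tumour   control      -0.68      8.97  1.18     0.26
         targeted      5.29     17.86  1.24     0.63
```

The targeted probe yields a positive mean tumour AUC₅₋₅₅ (retention), the
control probe a negative one (washout), and healthy pancreas — well
perfused but low in collagen — the most negative of all despite the highest
Enh5. The well-perfused mean SE curves show the same shapes: the targeted
curve keeps rising to 35 min (1.284 → 1.418) while the control falls
monotonically from its 5-min peak (1.266 → 1.110).

```python
print(report["correlations"][["biomarker", "r"]].round(2).to_string(index=False))
```

```
biomarker     r
 auc_5_55  0.91
 auc_0_55  0.14
     enh5 -0.76
 enh_last  0.99
  perf_vf -0.42
```

Against true tissue collagen, AUC₅₋₅₅ correlates strongly and positively
while the conventional AUC₀₋₅₅ barely correlates at all — the 5-min
reference has cancelled the delivery differences — and the
perfusion-driven quantities (Enh5, PerfVF) correlate negatively, as
expected when fibrosis impairs perfusion.

A `dceauc` command-line tool wraps the same steps:
`dceauc simulate`, `dceauc analyze`, `dceauc threshold`, `dceauc cohort`,
`dceauc coregister`, `dceauc validate`, `dceauc convert-dicom`.

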