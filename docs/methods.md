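# Methods

This note records the models, conventions and defaults the package
implements, and what its synthetic validation does and does not show.

## The analysis chain

Inputs are a 4D dynamic series (baseline at t = 0 plus post-injection
volumes with their actual acquisition times in minutes) and an integer ROI
volume on the same grid that must contain a dorsal-muscle reference label.

1. **Muscle normalization.** Every volume is divided by its mean
   dorsal-muscle signal, each time point individually. This removes
   per-acquisition scale factors (gain drift, loading); it makes the chain
   invariant to any per-timepoint multiplicative change, which is covered
   by a property test. Normalization is idempotent.
2. **Signal enhancement.** SE(v, t) = S(v, t)/S(v, 0) per voxel. Voxels
   with nonpositive baseline are flagged invalid and excluded from every
   downstream mean, count and pool (never silent infinities).
3. **AUC maps.** Trapezoidal integration of SE(t) − reference over a time
   window, using the *actual* acquisition times as nodes (nominal names
   like "5 min" are labels only). Two reference conventions:
   - `first-post` (AUC₅₋₅₅): reference is SE at the first post-injection
     sample; the area is signed. A flat curve gives exactly 0.
   - `baseline` (AUC₀₋₅₅): reference is 1, and when the window starts at 0
     the integration begins at the node (t = 0, SE = 1) — the baseline's
     enhancement against itself is 1 by definition.
   A window not fully covered by the available samples is clipped with a
   warning (acquisition times were approximate by design); fewer than two
   usable nodes is an error. AUC is additive over adjacent windows sharing
   a reference.
4. **Perfusion metrics.** Enh5 is SE at the first post-injection time. The
   perfusion threshold is the *median* Enh5 pooled over every analysed
   tissue voxel of every animal, both probe arms together (even-sized
   pools: mean of the two central order statistics). PerfVF is the
   fraction of ROI voxels with Enh5 **strictly** above the threshold —
   "surpassed" is read literally, so ties count as poorly perfused and the
   pooled PerfVF at the pooled median is 0.5 only up to tie effects.
5. **Specimen summaries.** Mean AUCs are taken over the **whole** tissue
   ROI (including necrotic regions); the displayed mean SE time courses
   are pooled over **well-perfused** voxels only, because poorly perfused
   voxels mostly add baseline noise to a curve display. Both conventions
   are explicit in the API (`summarize_specimen` vs `curve_mean_perfused`).
6. **Cohort statistics.** Mean ± SEM (SEM = sd/√n with ddof = 1); unpaired
   two-tailed Student's t-test with pooled variance and df = nₐ + n_b − 2
   (Welch behind a flag, not the default); Pearson correlation with a
   least-squares line for biomarker-vs-hydroxyproline associations; box
   plots as 0/25/50/75/100 percentiles; no multiple-testing correction.
   Zero pooled variance with equal means returns (t, p) = (0, 1) by
   convention. Joins that fail are reported, not dropped.

No inter-timepoint motion correction or kinetic-model fitting is applied
to analysed series: the AUC readout is deliberately model-free.

## The digital phantom and simulator

The simulator exists so every stage above can be tested against known
ground truth. It emulates the acquisition design of a collagen-targeted
probe study in a murine pancreatic-tumour model.

**Plasma input.** Cp(t) = Cp(0)·2^(−t/19 min), Cp(0) = dose / V_d with
dose 10 µmol/kg and V_d = 100 mL/kg (≈ blood volume plus fast early
distribution), i.e. Cp(0) = 100 µM. No bolus-dispersion phase is modelled:
the first sample is at 5 min, by which a dispersion transient is over.

**Tissue model** (per voxel, µM, min):

    dCf/dt = (Ktrans/ve)(Cp − Cf) − kon·Cf·(Bmax − Cb) + kon·Kd·Cb
    dCb/dt = kon·Cf·(Bmax − Cb) − kon·Kd·Cb
    Ct     = vp·Cp + ve·Cf + Cb

Two-compartment exchange plus reversible second-order binding;
koff ≡ kon·Kd is never an independent parameter. With Bmax = 0 the model
reduces to the standard exchange model and Cb ≡ 0. Binding capacity is
linear in collagen, Bmax = c·Hyp with c = 0.025 µM/(µg/g) — no site
density is known, so c is exposed and the linearity is itself an
assumption.

**Binding kinetics.** kon = 0.0015 µM⁻¹min⁻¹. At early free
concentrations (tens of µM) the binding relaxation rate kon·Cf + koff is
a few per minute — equilibration within minutes, fast relative to plasma
decay — while the off-rate alone, koff = kon·1.8 = 0.0027 min⁻¹, is slow.
This asymmetry is the retention mechanism: the bound pool loads while
plasma concentration is high and cannot unload on the 55-min time scale.
The control stereoisomer differs only in Kd (×100, the contractually
minimal affinity loss), which makes its koff fast and its bound pool a
small quasi-equilibrium amplifier of the free pool — it washes out.

**Tissue classes.** Parametric geometry (ellipsoids on a default
64×64×10 grid of 0.45×0.45×1 mm voxels, mirroring ten 1-mm slices; muscle
as a dorsal slab). Defaults per class:

| class    | Hyp µg/g (SD) | Ktrans /min | ve   | vp   | R1₀ /s |
|----------|---------------|-------------|------|------|--------|
| tumour   | 1224 (250)    | 0.10        | 0.20 | 0.04 | 0.60   |
| necrotic | 300 (80)      | 0.01        | 0.30 | 0.01 | 0.50   |
| pancreas | 523 (60)      | 0.50        | 0.50 | 0.15 | 0.60   |
| muscle   | 250 (30)      | 0.05        | 0.12 | 0.03 | 0.75   |

Collagen means are the reported group means for mature tumour and healthy
pancreas; the necrotic core is low-collagen by construction. Each tissue
class carries its own plasma fraction vp as well as ve: the healthy
pancreas is a highly vascular gland, and its large early delivery area
(high vp and distribution volume, fast exchange) against the fibrotic
tumour's delivery-limited uptake is precisely what makes the conventional
AUC₀₋₅₅ perfusion-dominated. A single global vp cannot produce that
regime. Collagen fields are class mean + SD × a unit-variance Gaussian
random field (correlation length 1.5 voxels, clipped at 0); Ktrans is
log-normal around the class mean (spatial σ_log 0.25).

**Between-animal variability.** Each specimen draws a collagen multiplier
(log-normal, σ = 0.35 — matching the reported tumour spread, SD ≈ 470 µg/g
on a mean of 1224) and a perfusion multiplier proportional to
collagen^(−1.5) times log-normal noise (σ = 0.5): more fibrotic specimens
are less perfused. The default cohort is 8 targeted tumours, 7 control
tumours and 3 targeted healthy-pancreas shams, the design of the source
study.

**Readout.** Linear relaxivity R1 = R1₀ + 16.2·[probe mM]; steady-state
SPGR signal S = M0·sinθ·(1 − E)/(1 − E·cosθ), E = exp(−TR·R1), with
TR = 92.6 ms and θ = 35°. TE/T2* decay is omitted: TE = 2.77 ms is short
and every analysed quantity is a ratio that cancels multiplicative
factors. Noise is Rician (magnitude of signal plus two independent
Gaussian channels, σ = 0.3 at M0 = 100, baseline SNR ≈ 45); σ = 0 returns
the input bit-identically, and all randomness is seed-parameterized.

**Ground truth.** Per-voxel class, collagen, Bmax, Ktrans and noiseless
concentration curves, plus a per-specimen table with the true mean
hydroxyproline and the simulated gadolinium at a configurable endpoint
(default 80 min, the euthanasia time), converted to nmol Gd per g wet
tissue as Ct[µM] × 3 Gd ions × 1 g/mL tissue density.

## Numerical choices

- The tissue ODE is integrated by fixed-step classical RK4 (substeps
  ≤ 0.02 min by default; 0.1 min in bulk simulation), vectorized over
  voxels; accuracy is verified against an independent 1-ms explicit-Euler
  reference to < 10⁻³ relative error. The system is non-stiff at all
  default parameters (fastest rate ≈ a few per minute).
- Tiny negative round-off in concentrations is clipped to 0.
- Trapezoids use `np.trapezoid` on the actual sample times; tests verify
  against explicit segment-by-segment summation.
- Registration searches a rotation × scale grid (NCC over translations via
  a matched filter), then refines around the best cell on two successively
  quartered grids. Deterministic; only positive NCC is maximized.
- Micrograph downsampling uses exact block averaging when the factor is
  integer and divides the image, area-preserving resampling otherwise;
  mean intensity is conserved to < 0.5 % for block-aligned factors.

## What the phantom shows — and what it cannot

Passing the synthetic-recovery suite demonstrates that the *analysis*
correctly extracts the sign structure and ordering the model generates:
positive tumour AUC₅₋₅₅ with the binding probe, negative with the control
and in healthy pancreas; enhancement rising to 35 min only with binding;
AUC₅₋₅₅ correlating with collagen far better than AUC₀₋₅₅ when perfusion
varies between specimens and anticorrelates with collagen; Enh5 and PerfVF
correlating negatively. It does not validate the biology: the phantom has
no partial-volume effects, no motion, no B1/coil inhomogeneity, no
anatomically realistic geometry, and no nonspecific retention — the last
is why the simulated control-probe endpoint gadolinium (~10 nmol/g) is
lower than measured in vivo, and why the last-timepoint enhancement
correlates with collagen more cleanly than real data would. Registration
recovery is shown for rotations up to ±30° and scales 0.8–1.2 on
synthetic mosaics; real SHG/MR pairs have contrast differences no
synthetic test exercises.

Problem sizes used throughout the test suite and the acceptance script —
64×64×10 phantoms, 18-animal cohorts, ≤ 10³-voxel oracle instances,
96×96 registration targets — were chosen so a full desk-side validation
runs in about a minute while keeping every ROI statistic well-sampled.
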