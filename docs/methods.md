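# Methods

This note documents the models, parameter choices, and numerical conventions
behind `gabasupp`, and what the synthetic-data tests do and do not establish
about real data.

## Spectral model and MRS quantification

**Acquisition constants.** 1,024 complex time-domain points per block at a
dwell time of 400 µs (2,500 Hz spectral width), transmit frequency
123.23 MHz (3 T), carrier on water at 4.70 ppm; 16 On + 16 Off blocks per
scan, each block a 10-transient average. TR/TE 1,500/68 ms and edit pulses
at 1.9/7.5 ppm are carried as metadata.

**Line shapes.** Metabolite resonances are Gaussian lines (Gaussian FID
decay), emulating shim-dominated in-vivo linewidths: creatine CH₃ at
3.00 ppm (6 Hz FWHM, unit amplitude), choline at 3.22 ppm (0.6, 6 Hz), NAA
at 2.01 ppm (1.5, 7 Hz), and a broad residual-water feature at 4.70 ppm
(0.4, 30 Hz). Gaussian rather than Lorentzian shapes keep tail leakage
outside the fixed integration windows below 1%, which is what makes simple
window integration a faithful quantifier; real Voigt-shaped spectra would
leak a few percent of heavy Lorentzian tail and shift the absolute ratio,
though not its ordering across subjects.

**Edited GABA.** The GABA feature is a pseudo-doublet at 3.00 ± 0.03 ppm
(J ≈ 7.3 Hz at 3 T, 6 Hz component width) present only in On-edited blocks,
so it survives in the On−Off difference. Because the doublet lies inside the
summed-spectrum creatine window (2.93–3.10 ppm), its amplitude is planted as
a_g = 2·a_Cr·R/(1−R) for a target ratio R, which accounts exactly for the
doublet's own contribution to the creatine area; noiseless recovery error of
the full chain is then < 1% (residual window-capture asymmetry).

**Noise and corruption.** Per-block complex white noise is scaled so the
creatine peak in the preprocessed spectrum has the requested amplitude SNR.
Each On/Off pair shares a random zero-order phase (±0.2 rad) and frequency
offset (±0.01 ppm), emulating slow drift; the creatine-referenced correction
must undo both.

**Correction.** The creatine peak is located within ±0.15 ppm of 3.00 ppm on
each Off block (magnitude argmax plus parabolic sub-bin refinement); the
phase is the angle of a matched-filter average over the line core
(deterministic Gaussian template, σ = 3 Hz). The estimated (phase, shift) is
inverted on the Off block and its paired On block via exact time-domain
modulation. On noise-free data the inversion is exact. On noisy data a
self-referencing bias remains: each Off block is rotated to maximize its own
real creatine content, which aligns its noise in the bins that the
difference spectrum then subtracts. This depresses the GABA estimate by
≈ 3% at block SNR 20 and < 0.2% at the default SNR of 120. The effect is
intrinsic to per-block self-referenced phasing (any estimator using the
block's own data in the integrated bins carries it) and is documented here
rather than hidden by calibration.

**Quality control.** Per frequency bin, mean and SD across same-state
blocks; a block's deviant count is the number of its bins beyond 2 SD (with
an absolute floor of 10⁻¹² of the data scale to ignore float rounding in
empty spectral regions). Blocks with more than `max_deviant` deviants are
excluded; QC never modifies retained data. The default `max_deviant = 300`
was chosen so clean synthetic data at default SNR lose < 1% of blocks
(observed per-block counts ≈ 140 ± 40 out of 4,096, because zero-padding and
apodization correlate neighboring bins). Note that with fewer than 7 blocks
per state no bin can mathematically exceed 2 SD (the maximum studentized
deviation is (n−1)/√n), so QC requires the full block count to have teeth.
Exclusion fractions are an observed outcome, not a target.

**Integration.** Trapezoidal rule over the real part, closed windows by bin
center: GABA 2.85–3.15 ppm in the difference, creatine 2.93–3.10 ppm in the
sum. Real-part integration (not magnitude) is the default; an optional
linear endpoint-baseline subtraction ships disabled. Per subject, GABA:Cr is
the mean over that subject's scans.

## Observer and staircase model

The simulated observer is a 4AFC Weibull,
p(correct | Δc) = 0.25 + (0.75 − λ)(1 − e^−(Δc/α)^β), with slope β = 3,
lapse λ = 0.02, and α the generating threshold of the cell. The transformed
2-up/1-down rule (two consecutive correct → increment ×10^−0.125, one error
→ ×10^+0.125) tracks the 70.7%-correct point (p² = ½); for this observer
that point sits at 0.995·α, so recovered thresholds estimate α nearly
directly. Staircases start at 10× the generating threshold (clipped to the
response ceiling 1 − pedestal = 0.70 Michelson), stop at 12 reversals or 400
trials, and are declared unmeasurable if pinned at the ceiling for 10
consecutive trials — mirroring observers who cannot detect any increment
under a maximal dichoptic surround. Steps before the first direction change
are not reversals; reversal averaging is geometric (log-domain), matching
the multiplicative step. Cell thresholds are geometric means over converged
staircases (4 per cell; fewer converged flags the cell unstable).

## Cohort generation

**Sample.** Defaults: 16 PWA, 15 NSP. PWA fellow-eye acuity uniform on
−0.20…0.08 logMAR and amblyopic-eye acuity on 0.12…1.26 logMAR, spanning the
clinical range of the packaged 16-row fixture; NSP acuities are near 0
logMAR with small jitter (no published control acuities exist, so this is a
modeling choice). Depth of amblyopia D = acuity_NDE − acuity_DE.

**GABA–depth coupling.** True GABA:Cr is 0.09 ± 0.004 (between-subject SD
consistent with a reported group SEM of 0.001 at n = 14). Among PWA, GABA
and D are coupled through a Gaussian copula with Pearson parameter
r = 2·sin(πρ_s/6) for a target Spearman ρ_s (default −0.61). The independent
uniform draw of fellow-eye acuity attenuates the realized correlation by
≈ 3%. The sensorimotor control voxel draws GABA independently.

**Measurement precision.** Default block SNR 120 with 4 scans per voxel
(8 per session across the two voxels) gives a per-subject GABA:Cr standard
error of ≈ 0.002 — measurement error well below the between-subject spread,
as required for a rank correlation of magnitude 0.6 to be detectable at
n = 14 at all. A noisier default would make the planted effect unrecoverable
by construction, contradicting the reported study outcome the generator
emulates.

**Baseline thresholds and surround weights.** Fellow-eye baseline increment
thresholds are log-normal around 0.03 Michelson; amblyopic-eye baselines are
elevated by a factor 1 + 1.5·D. Surround contrasts per subject are the
fellow-eye baseline × {2, 4, 6, 10} (capped at 0.95 Michelson), so tested
relative surround contrasts bracket the Ĉ\* ≈ 5 regime. Cell thresholds are
baseline × (1 + w·Ĉ) with condition weights w: iso > cross everywhere; in
PWA the dichoptic weight for annulus-in-NDE (fellow eye suppressing
amblyopic eye) is 0.90 vs 0.15 for the reverse, and monocular NDE > DE;
NSP weights are eye-symmetric. Multipliers are capped so generating
thresholds stay below the response ceiling. A `null_suppression_weights`
helper produces symmetric cohorts for false-positive checks.

## Suppression pipeline conventions

Nearest-point distances and reversal/threshold averaging operate in the log
domain (both quantities are multiplicative). The Ĉ\* candidate grid is 40
log-spaced values on [1, 20]; the score is the fraction of conditions whose
nearest-point mean T̂ exceeds 1, with ties broken by the between-eye
|Δ mean log Ĉ used| and then by closeness to the Ĉ values actually selected.
The full score table is emitted for audit rather than asserting a unique
optimum. Log-equidistant ties at extraction take the lower Ĉ. NSP eye
dominance ties break to the right eye with a warning. Missing cells
propagate as missing (pairwise deletion), never as subject exclusion.

## Inference conventions

Midranks for ties everywhere; two-tailed tests; sampled permutation p-values
use the +1 correction (never exactly zero), while exhaustive enumeration
(all n! shuffles or 2ⁿ label swaps, used automatically when cheaper)
includes the identity and needs none. The eye-difference test swaps each
subject's DE/NDE pair independently (exchangeable under the null of no eye
difference); the region-specificity test resamples subjects with replacement
by default (label permutation available). The ANOVA is a fixed-effects
factorial with Type-II sums of squares on the long table of selected T̂
values — with repeated measures per subject this treats subjects as fixed,
which inflates denominator df relative to a mixed model; it is used for the
planted-effect selectivity checks, not for p-value calibration. No
multiple-comparison correction is applied anywhere, deliberately.

## Problem sizes used in tests and the acceptance script

Simulated psychophysics cohorts use 6 PWA + 6 NSP (136 staircases/subject);
planted-correlation recovery uses 20 cohorts of 14 PWA at 4 scans each;
permutation calibration uses 500 null datasets of n = 12 at 2,000
permutations; the noisy-recovery Monte Carlo uses 50 subjects × 8 scans at
block SNR 20. These sizes keep the full suite and the acceptance script in
the minutes range while leaving every assertion's Monte-Carlo error well
inside its tolerance.

## What the synthetic tests do not show

The generator plants clean Gaussian-copula structure, Gaussian line shapes,
white spectral noise, a stationary observer, and exactly shared per-pair
drift. Real data add J-coupled multiplets and macromolecule background,
B0 drift within blocks, non-stationary lapses, and serial dependence between
staircases — so passing tests demonstrate the correctness of the analysis
machinery and its statistical calibration, not the physiological validity of
any particular parameter value. Absolute GABA:Cr values from window
integration are model-dependent (no water referencing or tissue correction);
only within-cohort comparisons are meaningful.
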