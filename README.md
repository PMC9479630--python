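# gabasupp

Analysis pipeline linking **visual-cortical GABA** (MEGA-PRESS magnetic
resonance spectroscopy, creatine-referenced peak integration) to
**psychophysical surround suppression** in amblyopia, exercised end-to-end on
synthetic cohorts with known ground truth.

In amblyopia, abnormal early visual experience leaves one eye (the amblyopic,
non-dominant eye, NDE) with reduced acuity, and perception in that eye is
suppressed by input from the fellow (dominant) eye far more strongly than the
reverse. The pipeline quantifies two measurements made in the same
individuals and the statistics that relate them:

* **GABA:Cr from edited MRS.** MEGA-PRESS alternates On (1.9 ppm) and Off
  (7.5 ppm) editing pulses; 10-transient block spectra are apodized with a
  4-Hz Gaussian, zero-padded 1,024 → 4,096 points, phase- and
  frequency-corrected against the creatine peak at 3.00 ppm (Off-derived
  corrections applied to paired On blocks), screened by an automated
  deviant-value tally (> 2 SD per frequency bin), and integrated: GABA over
  2.85–3.15 ppm in the On−Off difference spectrum, creatine over
  2.93–3.10 ppm in the summed spectrum. GABA:Cr is the ratio of those areas.
* **Surround suppression from adaptive staircases.** A 4AFC
  contrast-increment task (which annulus quadrant exceeds the 30% pedestal)
  driven by a transformed 2-up/1-down staircase in 0.125-log₁₀ steps, which
  converges at the 70.7%-correct point; each staircase ends after 12
  reversals and its threshold is the geometric mean of the last six.
  Thresholds with a surround are normalized by the same eye's no-surround
  baseline T₀: relative threshold T̂ = T/T₀ and relative surround contrast
  Ĉ = C/T₀. A single reference contrast Ĉ\* is chosen data-driven (suppression
  reliably evoked, eyes treated symmetrically); each condition contributes
  its point nearest Ĉ\* in log Ĉ. The NDE:DE ratio R = T̂_NDE/T̂_DE and the
  orientation-selectivity ratio Q = T̂_iso/T̂_cross isolate the surround's
  effect from baseline acuity differences.
* **Inference.** Spearman ρ with 100,000-sample permutation nulls, paired
  DE/NDE label-swap tests, subject-resampled region-specificity tests,
  Fisher r-to-z comparison of two correlations, bootstrap confidence bands
  for linear fits, one/two-sample t-tests, Cohen's d, and the omnibus
  factorial ANOVA (orientation × ocular configuration × eye × group).

Because the study's raw data are not needed, a first-class synthetic-cohort
module generates clinical tables, MEGA-PRESS scan bundles, and trial-level
staircase logs with planted effects — a Gaussian-copula rank correlation
between GABA:Cr and depth of amblyopia (D = logMAR NDE − DE), and eye-,
configuration- and orientation-specific surround weights — so every stage is
testable against ground truth.

## Worked example

```python
import numpy as np
from gabasupp import mrs
from gabasupp.cohort import CohortSpec, synthesize_scan
from gabasupp.pipeline import run_cohort_pipeline
from gabasupp.stats import fisher_z_compare

# Quantify one synthetic scan with a planted GABA:Cr of 0.09, noise-free
est = mrs.gaba_cr_ratio(synthesize_scan(0.09, snr=np.inf, seed=1))
print(f"GABA:Cr = {est.gaba_cr:.4f} from {est.n_blocks_used} blocks")
# GABA:Cr = 0.0896 from 32 blocks   (planted 0.09, recovered within 2%)

# Compare two correlations the way voxel specificity is tested
res = fisher_z_compare(-0.61, 14, 0.10, 11)
print(f"|z| = {abs(res.z):.2f}, p = {res.p_two_tailed:.2f}")
# |z| = 1.74, p = 0.08

# A whole simulated study: cohort -> scans -> staircases -> ratios -> stats
result = run_cohort_pipeline(CohortSpec(n_pwa=6, n_nsp=6, seed=11), n_perm=2000)
print(result["stats"]["gaba_depth_correlation"]["visual"])
# {'rho': ..., 'n': 6, 'p_perm': ...}  rank correlation of measured GABA:Cr
#                                      with depth of amblyopia among PWA
```

The first number shows that the quantification chain (preprocessing,
creatine-referenced correction, QC, window integration) returns a planted
metabolite ratio; the second reproduces the Fisher r-to-z comparison between
a visual-cortex correlation (ρ = −0.61, n = 14) and a sensorimotor control
(ρ = 0.10, n = 11); the third runs the full study on a synthetic cohort.

A command-line interface mirrors the stages: `gabasupp quantify-mrs`,
`gabasupp fit-thresholds`, `gabasupp analyze-suppression`, `gabasupp stats`,
and `gabasupp run-all` (see `--help` on each).

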