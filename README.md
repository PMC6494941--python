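# mpqmri

Multi-parametric quantitative MRI analysis for retroperitoneal soft-tissue
sarcoma: voxel-wise diffusion, relaxometry, fat-fraction and
contrast-enhancement parameter estimation; whole-tumor histogram summaries;
double-baseline test–retest repeatability; radiotherapy-response calls; and
imaging–histopathology correlation. A synthetic multi-parametric phantom
generator provides fully controlled inputs with the same statistical
structure as the clinical acquisitions, so every stage of the pipeline can
be exercised and validated without patient data.

## Who this is for

Imaging scientists and trial methodologists who need quantitative MRI
biomarkers (ADC and friends) for characterising heterogeneous tumors and
detecting treatment response beyond size criteria — soft-tissue sarcomas
being the motivating case, where responding tumors often do not shrink and
RECIST 1.1 calls them stable.

## The models and statistics at the core

**Diffusion.** The diffusion-weighted signal is fitted voxel-by-voxel with
a Levenberg–Marquardt mono-exponential, S(b) = S0·exp(−b·ADC), and with the
intra-voxel incoherent motion (IVIM) bi-exponential

    S(b) = S0 · [ (1 − f)·e^(−b·D) + f·e^(−b·D*) ],

sampled by Markov-chain Monte Carlo with uniform priors and the constraint
D* > D; point estimates are posterior medians. A two-point b-value design
helper returns the optimal upper weighting b = 1.1/ADC.

**Relaxometry, fat, enhancement.** R2* from a multi-echo gradient-echo
mono-exponential; Dixon fat fraction FF = fat/(fat + water); enhancing
fraction EF (% of VOI voxels rising > 5% after contrast) and fractional
enhancement ε_F = (S1 − S0)/(S1 + S0).

**Repeatability.** With d_i = ln x_i2 − ln x_i1 over N double-baseline
patients, the within-subject SD is s_W = sqrt(Σ d_i²/2N), and

    CoV  = 100%·sqrt(exp(s_W²) − 1),
    LoA± = 100%·(exp(±1.96·√2·s_W) − 1).

A post-treatment change outside the 95% LoA is a significant individual
response. Cohort changes use Wilcoxon signed-rank tests; group contrasts
use rank-sum tests; imaging–histology association uses Spearman's rho with
Fisher-z confidence intervals.

## Worked example

```python
import numpy as np
from mpqmri.phantom import (PhantomSpec, RepeatCohortSpec, default_tumor_geometry,
                            generate_phantom, synthesize_acquisitions, add_rician_noise,
                            noise_sigma_for_snr, simulate_repeat_cohort)
from mpqmri.fitting import apply_signal_threshold, fit_monoexponential, recommend_upper_b
from mpqmri.voi import VOIMask, summarize_map
from mpqmri.repeatability import repeatability_metrics

shape = (32, 32, 10)
spec = PhantomSpec(grid_shape=shape, tumor_geometry=default_tumor_geometry(shape),
                   target_snr=386.0, seed=7)
vols = generate_phantom(spec)
series = synthesize_acquisitions(vols)
sigma = noise_sigma_for_snr(series["dwi_adc"], vols.tumor_mask, 386.0)
noisy = add_rician_noise(series["dwi_adc"], sigma, seed=7)

excluded = apply_signal_threshold(noisy, noise_sd=sigma, k=3.0)
adc_map, diag = fit_monoexponential(noisy, vols.tumor_mask & ~excluded, min_encoding=50.0)

voi = VOIMask(vols.tumor_mask, spec.voxel_size)
s = summarize_map(adc_map, voi)
print(f"median ADC = {s.median:.3e} mm^2/s over {s.n_voxels} fitted voxels "
      f"({s.volume_cm3:.1f} cm^3 tumor)")

cohort = simulate_repeat_cohort(RepeatCohortSpec(seed=7))
rep = repeatability_metrics(cohort["baseline1"], cohort["baseline2"], statistic="median_ADC")
print(f"CoV = {rep.cov_pct:.1f}%  LoA = (+{rep.loa_upper_pct:.1f}%, {rep.loa_lower_pct:.1f}%)")
print(f"upper b-value for ADC 1.70e-3: {recommend_upper_b(1.70e-3)} s/mm^2")
```

prints

```
median ADC = 1.101e-03 mm^2/s over 730 fitted voxels (14.6 cm^3 tumor)
CoV = 2.4%  LoA = (+6.8%, -6.4%)
upper b-value for ADC 1.70e-3: 647 s/mm^2
```

The tumor's dominant (cellular) class has a true ADC of 1.10×10⁻³ mm²/s,
so the whole-tumor median is recovered to within the noise at SNR 386; the
27-patient simulated double-baseline cohort (within-subject log-SD 0.025)
yields a CoV near 2.5% with 95% limits of agreement near +7/−7%, the band
against which individual post-radiotherapy changes are judged; and a tumor
with ADC 1.70×10⁻³ mm²/s is best interrogated by a two-point scheme whose
upper b-value is 1.1/ADC ≈ 647 s/mm².

A full end-to-end run (phantom → noisy acquisitions → all fits → VOI
summaries → repeatability/response/correlation reports, with NIfTI/CSV
artifacts and a JSON manifest) is one command:

```sh
mpqmri run-all --out demo_run --seed 1
```

## Layout

- `mpqmri.phantom` — digital tumors, acquisition synthesis, Rician noise, cohort and histology simulators
- `mpqmri.fitting` — signal thresholding, mono-exponential and IVIM-MCMC fits, FF/EF/ε_F, SNR, b-value design
- `mpqmri.voi` — VOI assembly, histogram summaries, fat-dominance exclusion
- `mpqmri.repeatability` — s_W/CoV/LoA with confidence intervals, Bland–Altman points, individual change calls
- `mpqmri.response` — signed-rank tests and cohort response tables
- `mpqmri.correlation` — Spearman correlation with CIs, rank-sum tests, fat-ROI filtering
- `mpqmri.pipeline` / `mpqmri.cli` — orchestration and the `mpqmri` command

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical conventions.
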