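# zebrafit

Combined T2\*–diffusion relaxometry mapping for placental MRI: voxelwise
fitting of joint (b, TE) signal models to multi-echo diffusion-weighted
volumes, whole-organ summaries, and gestational-age cohort statistics.

## The problem

Placental function (oxygenation, probed by T2\*) and microstructure
(water mobility, probed by the apparent diffusion coefficient, ADC) are
usually imaged separately and analysed cross-sectionally. An integrated
multi-TE diffusion acquisition (the "ZEBRA" technique) samples the joint
(b-value, echo-time) space in a single scan — here 60 diffusion
preparations, each read out at TE = 78, 114, 150, 186 ms, for 240
measurements per voxel — which lets a single model estimate relaxation
and diffusion parameters simultaneously. `zebrafit` is for researchers
who have such data (or want to prototype against realistic synthetic
data) and need reproducible parameter maps, whole-placenta metrics, and
cohort-level statistics of how those metrics evolve over gestation,
including the *within-subject* consistency of rates of change.

## Models

Two isotropic voxel models, with TE entering through the offset from the
shortest acquired echo time TE_min so that S0 is the observed signal at
(TE_min, b = 0):

**T2\*-ADC** (single compartment)

    S(TE, b) = S0 · exp(−(TE − TE_min)/T2*) · exp(−b·ADC)

**T2\*-IVIM** (bicompartmental intravoxel incoherent motion)

    S(TE, b) = S0 · [ f · exp(−b·D*) · exp(−(TE − TE_min)/T2*_P)
                    + (1 − f) · exp(−b·ADC) · exp(−(TE − TE_min)/T2*_D) ]

where f is the perfusion fraction, D\* the pseudo-diffusion coefficient
of the perfusing compartment (restricted to at least the free-water
diffusivity, 3.0×10⁻³ mm²/s, so the fast/slow labelling is
unambiguous), and T2\*_P / T2\*_D the compartment relaxation times.
Fitting is "brute2fine": an exhaustive grid search over the nonlinear
parameters (S0 profiled out in closed form) seeds a bounded nonlinear
least-squares refinement. The IVIM fit also yields fraction-weighted
maps (f·T2\*_P, (1−f)·ADC, …) and their combined weighted sums.

Cohort statistics follow the standard design: ordinary least squares of
each whole-placenta metric on gestational age (slope, R², two-sided p
with n−2 df) for subjects scanned once, per-week rates of change for
subjects scanned twice, and the signed coefficient of variation
SD/mean of those individual rates ("covariance") as the consistency
measure — consistent when |SD/mean| < 1, significant when p < 0.05.

## Worked example

Fit one noisy voxel (SNR 100 at TE_min) and run the cohort statistics on
a simulated 62 + 17-pair cohort:

```python
import numpy as np
from zebrafit import (default_zebra_scheme, T2sIVIMParams, t2sivim_signal,
                      DiffusionRelaxometryFit, simulate_cohort, CohortSpec,
                      cohort_report)

scheme = default_zebra_scheme()                      # 240 measurements
truth = T2sIVIMParams(s0=100.0, f=0.30, d_star=30e-3, t2s_p=85.0,
                      adc=1.6e-3, t2s_d=95.0)
rng = np.random.default_rng(0)
signal = t2sivim_signal(truth, scheme) + rng.normal(0.0, 1.0, len(scheme))

est = DiffusionRelaxometryFit(model="t2s_ivim").fit(scheme, signal)
p = est.params_

cross, pairs, _ = simulate_cohort(CohortSpec(), seed=1)
report = cohort_report(cross, [o for pr in pairs for o in pr],
                       metrics=("t2s_adc.t2s",))
```

Printed output:

```
f = 0.292, D* = 29.5 x10-3 mm2/s, T2*p = 93.1 ms, ADC = 1.61 x10-3 mm2/s, T2*d = 93.9 ms
converged = True, residual = 239.1
slope = -2.77 ms/wk, R2 = 0.61, p = 5.52e-14; within-subject -3.26 +/- 1.21 ms/wk, consistency = -0.37
```

The voxel fit recovers the generating perfusion fraction and
diffusivities to a few percent at this noise level (the compartment T2\*
values are the least stable parameters, as expected for a
six-parameter bicompartmental model). The cohort report finds the
configured T2\* decline of ≈ −2.5 ms/week with R² ≈ 0.6, and the
within-subject rates of change agree with each other (|SD/mean| < 1),
i.e. the decline is consistent across individual pregnancies.

The same pipeline is scriptable from the shell:

```bash
zebrafit simulate phantom --shape 10,10,4 --model t2s_ivim --out-dir phantom/
zebrafit fit --image phantom/series.nii.gz --mask phantom/mask.nii.gz \
             --scheme phantom/scheme.txt --model t2s_ivim --out-dir maps/
zebrafit summarize --maps-dir maps/ --out metrics.csv --ga-weeks 30
zebrafit cohort --metrics cohort_metrics.csv --out report.csv
```

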