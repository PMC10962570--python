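# Methods

## Signal models

Both models describe the magnitude signal of a voxel sampled jointly in
diffusion weighting b (s/mm²) and echo time TE (ms). Echo time enters
only through (TE − TE_min), where TE_min is the shortest echo time of
the scheme, so the scale parameter s0 is the *observed* signal at
(TE_min, b = 0) rather than an extrapolated TE = 0 magnetisation. This
convention is deliberate and load-bearing: fitted s0 values are
comparable across protocols only at equal TE_min.

* `t2s_adc`: one compartment, `s0·exp(−(TE−TE_min)/t2s − b·adc)`.
* `t2s_ivim`: two compartments sharing a single s0 and split by the
  perfusion fraction f; the perfusing compartment decays with the
  pseudo-diffusion coefficient `d_star` and relaxation time `t2s_p`,
  the tissue compartment with `adc` and `t2s_d`. No per-compartment
  proton-density scaling; the two T2\* values may coincide, in which
  case f, d_star and adc carry all the contrast.

Units: ms for relaxation times, mm²/s for diffusivities (typical tissue
ADC ≈ 2×10⁻³ mm²/s). Reporting layers may use the conventional 10⁻³
mm²/s display scale; all internal computation is in base units.

## Default acquisition scheme

The built-in protocol reproduces an integrated multi-TE diffusion
("ZEBRA") placental acquisition: 3 gradient directions at each of
b = 5, 10, 25, 50, 100, 200, 400, 600, 1200, 1600 s/mm², 8 directions at
b = 18, 7 at b = 36, 15 at b = 800 — 60 preparations, each read at
TE = 78, 114, 150, 186 ms, i.e. 240 measurements, TE_min = 78 ms.
Directions are not tabulated in the source protocol (only per-shell
counts); both models are isotropic so directions never enter the
signal, and the scheme generates them with a deterministic golden-angle
spherical spiral per shell purely so files round-trip reproducibly.
Scheme files are plain text, five columns `gx gy gz b TE_ms` with `#`
comments — a minimal extension of the bval/bvec convention carrying the
TE column this method needs. The acquisition's nominal voxel size is
3 mm isotropic, the default on `VolumeSeries`.

A note on the protocol table as published: it prints "TR = 7.5 ms",
which cannot be a volume repetition time for a spin-echo EPI sequence
(plausibly 7.5 s). TR enters neither model, so it is not represented.

## Fitting ("brute2fine")

The objective is the unweighted Gaussian sum of squared residuals —
matching the original analysis; Rician-likelihood fitting is explicitly
out of scope (the simulator can still *generate* Rician noise so the
mis-specification can be studied).

1. **Grid stage.** The forward model is evaluated on a coarse grid over
   the nonlinear parameters. At each grid point the model is linear in
   s0, so s0 takes its closed-form least-squares value (clipped at 0)
   and is never gridded — this removes one grid dimension without
   changing the optimum. The full (grid × measurement) design matrix is
   precomputed once per (model, grid, scheme) and shared across voxels;
   for the default IVIM grid it is 12 000 × 240.
2. **Refinement.** Bounded trust-region-reflective least squares
   (`scipy.optimize.least_squares`) over all parameters including s0,
   started from the best grid point. Defaults: `ftol = 1e-10`,
   `xtol = 1e-12`, at most 500 iterations; all configurable via YAML.
   The refinement never returns a point worse than its initializer, and
   non-convergence is reported as a flag, never an exception. With
   `n_starts > 1` (default 3) the refinement is repeated from the next
   best grid points and stopped early once a run converges with an
   essentially exact fit; ties keep the earlier start, so fitting is
   fully deterministic.

Default grids (coarse but covering the published placental range):
T2\* values {20, 40, …, 200} ms; ADC {0.5, 1.0, …, 3.0}×10⁻³ mm²/s;
D\* {5, 10, 20, 50, 100}×10⁻³ mm²/s; f {0.1, 0.3, 0.5, 0.7}. Refinement
bounds: T2\* ∈ [5, 500] ms, ADC ∈ [0, 3×10⁻³], D\* ∈ [3×10⁻³, 0.5]
mm²/s, f ∈ [0, 1], s0 ≥ 0.

**Fast-compartment restriction.** The pseudo-diffusion coefficient is
bounded below by `fast_adc_lower_bound`, default 3.0×10⁻³ mm²/s — the
diffusivity of freely diffusing water at body temperature. Because this
equals the upper bound on the tissue ADC, the compartments cannot
exchange labels during optimisation: the faster compartment is always
"perfusing". The bound is configurable for sensitivity analyses.

**Degenerate voxels.** All-zero or non-finite signals raise a
degenerate-input error at the single-voxel API; volume fitting catches
it, flags the voxel non-converged, stores NaN, and continues. Summaries
exclude failed voxels and always report the usable-voxel count; NaN is
the missing code in every NIfTI output.

## Maps and summaries

For the bicompartmental model the fraction maps weight the compartment
maps: f·T2\*_P, f·D\*, (1−f)·T2\*_D, (1−f)·ADC, and the combined sums
f·T2\*_P + (1−f)·T2\*_D and f·D\* + (1−f)·ADC. Raw and weighted sets are
both retained because "compartment T2\*" is reported both ways in the
literature; summaries name them explicitly (`ivim.t2s_perf` vs
`ivim.t2s_perf_weighted`). The whole-placenta value of a map is the
arithmetic mean over converged in-mask voxels (a median alternative is
available behind the `statistic` switch but is not the default).

## Cohort statistics

* Cross-sectional: OLS of metric on gestational age (GA, weeks) via
  statsmodels; R² = 1 − SS_res/SS_tot; two-sided slope p-value from the
  t distribution with n − 2 df. Degenerate case SS_tot = 0 is defined
  as slope 0, R² = 0, p = 1. Requires n ≥ 3 and non-constant GA.
* Within-subject rate of change: (value₂ − value₁)/(GA₂ − GA₁) with
  scans ordered by GA; subjects must contribute exactly two scans
  (the study design) — a third scan raises an error rather than being
  silently regressed.
* Consistency ("covariance" in the clinical literature): the signed
  ratio SD/mean of the individual rates of change, sample SD with n − 1.
  This is the only reading consistent with every published
  mean ± SD / covariance triple (1.44/3.057 → 0.47, 2.34/2.71 → 0.863,
  1.93/0.75 → 2.57). The signed value is stored; the significance rule
  applies strictly to its absolute value (|SD/mean| < 1 consistent,
  p < 0.05 significant; both strict inequalities). No multiple-testing
  correction is applied, matching the source analysis. Inclusion range
  for GA is [20, 42] weeks.

## Synthetic data

The generator exists because no cohort data are deposited; its defaults
*are* the study conditions, not free dials.

* **Voxel noise**: Gaussian (additive) or Rician
  (`hypot(signal + n₁, n₂)`); at zero signal the Rician mean is
  σ·√(π/2), at high SNR the inflation is ≈ σ²/2A — both verified by
  Monte-Carlo tests.
* **Phantoms**: ellipsoidal mask inscribed in the grid; per-voxel truth
  = base value × (1 + a·smooth), with `smooth` a seeded sum of
  low-frequency cosine modes normalised to [−1, 1] (default amplitude
  a = 0.10), optionally multiplied on the T2\* fields by a lobule
  modulation that depresses T2\* along Voronoi boundaries between
  seeded lobule centres — mimicking the hypointense rims between
  hyperintense lobules seen on placental maps. Base values (e.g. IVIM:
  f = 0.30, D\* = 30×10⁻³ mm²/s, T2\*_P = 85 ms, ADC = 1.6×10⁻³ mm²/s,
  T2\*_D = 95 ms) sit mid-gestation in the published placental range.
  Heterogeneity that would leave the fitting bounds raises an error
  rather than being clipped.
* **Cohorts** (metric-level): GA ~ N(30.72, 4.74²) truncated to
  [20, 42] by rejection for the 62-subject cross-sectional arm; the 17
  longitudinal pairs draw first scans from N(27.23, 3.00²) and
  inter-scan intervals from N(6.87, 1.5²) (interval SD is a convention;
  only the mean is published), resampled until GA₂ ≤ 42. Each metric
  follows value_at_ref + slope·(GA − 28) with a subject random
  intercept, a subject-specific slope drawn around the population
  slope, and independent scan-level noise.

### Generator calibration

Population slopes default to the published cross-sectional values
(T2\*: −2.54 ms/wk; ADC: −0.03×10⁻³ mm²·s⁻¹/wk — ADC slopes are read on
the 10⁻³ scale, since a literal mm²/s reading is physically impossible
for tissue; perfusing/diffusing T2\*: −2.35 / −1.91 ms/wk; f:
+0.5 %/wk). Subject slope dispersions default to the published
longitudinal SDs (e.g. 1.44 ms/wk for T2\*). Cross-sectional scatter is
back-solved from the published R²: σ_res = |slope|·σ_GA·√((1−R²)/R²)
with σ_GA = 4.74 wk, split into a between-subject intercept SD and a
smaller scan-level SD (2.5 ms for T2\* metrics — a scan–rescan scale for
a whole-organ mean; analogous small values for ADC-type metrics and f).
Absolute levels at the 28-week reference (T2\* 90 ms, ADC 1.8×10⁻³,
f 0.32, …) are *conventions*: no absolute values are published for this
protocol, so they are chosen to be physiologically reasonable, clearly
configurable, and never used as test oracles.

Because measured within-subject slopes carry measurement noise
(variance 2σ_w²/ΔGA² on top of the configured slope dispersion), the
statistical-recovery checks compare the configured dispersion/mean
ratio against the standard moment-matched estimate — subtract the known
noise variance from the measured slope variance before taking SD/mean —
rather than pretending the noise does not exist or switching it off.

### What the generator does not emulate

Motion, bias fields, uterine contractions, partial-volume mixtures,
anatomically realistic vasculature, registration error between scans,
or covariate structure (BMI, maternal age). Passing recovery tests on
this generator therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to acquisition artefacts —
the in-vivo analysis delegates those to upstream motion/bias
correction.

## Problem sizes and numerical choices

The verification suite runs at desk scale by design: phantoms are
10×10×4 (≈ 216 in-mask voxels) and noiseless model inversion uses 100
parameter draws per model — the per-voxel fit is identical at any
volume size, so nothing about correctness depends on the grid being
small. Statistical recovery uses 100 replicated cohorts at the full
published cohort geometry (62 + 17×2 scans), which is metric-level and
cheap. Determinism everywhere: no internal randomness in fitting;
every simulation consumes an explicit integer seed; grid-search and
multi-start ties break toward the lower index / earlier start.

## Known limitations

* Compartment T2\* values of the six-parameter IVIM model are weakly
  identified at low f or when the compartments are similar; at
  realistic noise their per-voxel error is substantially larger than
  for the simpler model's parameters (whole-organ means are much more
  stable).
* The Gaussian objective is mis-specified at low SNR where MR magnitude
  noise is Rician; the fitted parameters inherit the usual noise-floor
  bias. The simulator can generate Rician data to quantify this, but
  Rician-likelihood fitting is deliberately not implemented.
* Only a linear GA model is provided; sigmoidal trajectories reported
  for wider GA windows are out of scope.
* No spatial regularisation or model selection (e.g. BIC) across
  models.
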