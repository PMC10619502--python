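# Methods

This note documents the models and procedures `lcsleep` implements, the
choices made where the underlying methodology leaves room, and what the
synthetic generators do and do not emulate.

## LC contrast

The LC appears hyperintense on magnetization-transfer-weighted images
(typical acquisition: ~0.4 × 0.4 × 0.5 mm³ voxels, axial slices
perpendicular to the floor of the fourth ventricle). Given a
co-registered volume and a binary mask per side:

- **Skeletonization** keeps, per axial slice intersecting the mask, the
  in-mask voxel of maximal intensity. Ties are broken toward the
  smallest (row, col) coordinate in row-major order, so results are
  deterministic and platform independent. Slices the mask does not
  touch are omitted; an empty mask or a grid mismatch is an error.
- **Reference region**: a square of 15 × 15 in-plane voxels
  (≈ 5.5 × 5.5 mm² at this resolution) placed in the pontine tegmentum.
  Centers are user input (YAML: slice → [row, col]); there is no
  automatic anatomical placement, because the anatomical rule ("anterior
  and central in the pons") does not determine coordinates. A square
  clipped by the grid is an error rather than a partial average — and a
  slice with a skeleton entry but an invalid reference square aborts the
  computation rather than being dropped, since silent slice dropping
  would bias the slice mean.
- **Contrast**: per slice, `(LC_i − mean(pons_i)) / mean(pons_i)`; the
  side contrast is the arithmetic mean of per-slice ratios, and the
  bilateral contrast the mean of the two sides. Averaging per-slice
  ratios (rather than taking a ratio of slice-averaged quantities)
  follows from the per-slice normalization the symbol definitions
  describe; with a spatially uniform reference the two readings agree.
  Negative contrasts are allowed; a non-positive reference mean is an
  error because the normalization is then undefined.

The contrast is invariant to global intensity scaling and covaries in
the documented way under intensity shifts; both properties are tested.
Inputs are assumed co-registered — the upstream registration,
up-sampling and manual delineation steps of a real study are outside
this package's scope. The cross-participant contrast distribution can be
summarized with a Gaussian kernel density (`contrast_density`, SciPy's
`gaussian_kde`, Scott bandwidth unless overridden).

## Sleep metrics

Hypnograms are 30-s epochs labeled W/N1/N2/N3/REM with a
lights-off/lights-on window; epochs only partially inside the window are
excluded entirely. Sleep onset is the first non-wake epoch of any stage
(configurable in principle, but no stricter N2-based rule is assumed).
TST counts non-wake epochs; efficiency is 100·TST/time-in-bed; REM% is
relative to TST. REM latency runs from the first sleep epoch to the
first REM epoch; REM episodes are maximal runs of REM epochs, with an
optional merge window for short interruptions (default 0 = strict
runs); "arousals during REM" counts annotation *events* overlapping at
least one REM epoch, not epochs.

**Band power** uses Welch's estimator with 4-s Hann segments and 2-s
overlap (density scaling); band power is the PSD summed over bins with
`lo ≤ f < hi` times the bin width. A unit-amplitude in-band sinusoid
yields ≈ A²/2 = 0.5 µV².

**Cumulative energy** (SWE, REM theta): segments are 4-s windows
aligned to epoch boundaries at a 2-s step, restricted to target-stage
epochs; a segment is *clean* only if it overlaps no annotated
arousal/artifact interval at all (strict exclusion). Per 30-min bin —
anchored at lights off — the clean-segment mean power is multiplied by
(target-stage epochs in bin)/(epochs per bin), and the energy is the
sum over bins. This stage-time weighting is the "adjustment for the
proportion of rejected data": rejecting half the segments of a
stationary record changes neither the clean mean nor the weight, so the
cumulated sum is unbiased by rejection (tested to 5%). A flag
(`adjust_for_rejection=False`) switches to the unweighted clean-mean
sum for comparison. Bins whose target stage is present but with zero
clean segments are flagged, excluded from the sum, and warned about; a
record with no target-stage epoch at all gives an explicit undefined
result rather than zero.

SWE's stage set is N3 only by default ("SWE during SWS"), with
`("N2","N3")` available since NREM-wide cumulation is also common. A
single frontal channel is the expected input (the caller selects the
EDF channel label; CSV carries one channel).

## Synthetic generators

All generators are pure functions of (spec, seed) — bit-identical
outputs for identical inputs — and return ground-truth records
sufficient to predict every downstream result without rerunning them.

- **LC phantom**: constant pontine background plus optional Gaussian
  noise; per side, an ordered centerline (≤ 1 voxel per slice) set to
  the LC intensity; masks dilate the centerline by 1 voxel in-plane so
  the centerline is the in-mask maximum when noise is small. With zero
  noise the downstream contrast equals
  `(lc_intensity − background)/background` exactly on every slice.
- **Hypnogram**: stage counts from the spec proportions
  (largest-remainder rounding), wake prefix of `sleep_onset_epoch`
  epochs, REM placed by an explicit bout plan (or evenly derived from
  the REM fraction), remaining stages filled in shuffled runs; realized
  proportions land within ~2 percentage points of the spec. Arousal
  events are Poisson at a given rate/hour (3–15 s); artifacts mark a
  given fraction of 4-s slots.
- **EEG**: per stage, white noise is FFT-masked to each canonical band
  and rescaled to the exact target band variance, then dealt into that
  stage's epochs; broadband noise is added on top. Filtered white noise
  was chosen over AR fits to real EEG because it has analytically known
  band powers. Artifact spans are multiplied by 10 — an unambiguous
  signature whose content is irrelevant because artifacts are excluded
  by annotation, not detected. Defaults (e.g. N3 delta 160 µV², REM
  theta 20 µV², W/N1/N2 intermediate) are plausible placeholder levels,
  not calibrated to any cohort, since per-stage spectral levels are not
  part of the emulated study's report. No spindles, K-complexes or 1/f
  morphology: passing tests show estimator correctness on band-limited
  Gaussian signals, not robustness to real-EEG nonstationarity.
- **Cohort**: two groups (defaults 33 young, 19 old, ~3/4 women,
  BMI ~ N(23, 2.5), TST ~ N(420, 35) minus 20 min in the older group),
  LC activity ~ N(0, 1). The sqrt-scale mediator (REM theta) is
  `m0 + (a + slope_g)·X + covariates + ε` and is stored **squared**, so
  the square-root transform used downstream is exercised; the
  subjective-sleep outcome is
  `p0 + (c′ + slope_g)·X + b·M_c + γ·X·M_c + covariates + ε` with `M_c`
  the centered sqrt-scale mediator. Group slopes and mediation
  coefficients compose additively: with a = b = γ = 0 the slopes are a
  pure interaction plant; with slopes = 0 the a/b/c′/γ coefficients are
  the textbook linear mediation. The other sleep outcomes are
  covariate-plus-noise nulls, giving nominal-α behavior for the
  multiple-testing machinery.

## Statistics

- **Model family.** The emulated analysis described its models as GLMMs
  with participant as a random factor, but with one observation per
  participant a random intercept is confounded with the residual and
  not identifiable; the models here are fixed-effects linear models.
  Default family is Gaussian (identity link); a log-link Gamma family
  is available for right-skewed positive energy outcomes. The family
  used is recorded in every report.
- **Interaction models.** `outcome ~ predictor * moderator +
  covariates`, binary moderator, alphabetically first level as
  reference. All tested terms are single-df with a binary moderator, so
  the Wald F = t² per coefficient is the Type-III test. Effect size is
  partial R² = F·df₁/(F·df₁ + df₂). Rank deficiency raises an error
  naming the collinear columns. Simple slopes come from the linear
  contrast `β_pred + β_int·1[group]` with its delta-method SE; they are
  invariant to which level is the reference (tested).
- **BH-FDR** is the standard step-up rule, implemented directly because
  the critical-p output (largest p(k) ≤ k·q/m) is part of the contract;
  it is verified against both a brute-force enumeration and
  statsmodels' `fdr_bh` adjusted p-values. The default FDR family is
  the six interaction p-values of the primary models (configurable to
  the predictor main effects).
- **Primary battery.** Six outcomes — PSQI, sleep onset latency,
  efficiency, REM%, SWE, REM theta energy — with sex and BMI as
  covariates, plus TST for the two cumulative-energy outcomes (their
  sums grow mechanically with time in stage).
- **Mediation.** Linear working models — mediator ~ exposure +
  covariates; outcome ~ exposure + mediator + exposure×mediator +
  covariates — and the linear counterfactual formulas for a one-unit
  exposure change from the sample mean. The controlled direct effect
  fixes the mediator at its covariate-adjusted mean (the fitted
  mediator at the reference exposure); the pure indirect effect uses
  the reference-level interaction weighting; the total effect is
  NDE + TIE. With no interaction these reduce exactly to CDE = c′ and
  PIE = a·b (tested to 1e-6 against separately fitted coefficients).
  Inference is nonparametric case-resampling bootstrap with percentile
  CIs; the seed is mandatory. When the bootstrap 95% CI of the total
  effect includes zero the result is flagged `unstable`, because
  percentages of a near-zero total effect are not interpretable. An
  optional square-root transform handles energy mediators generated on
  the squared scale.
- **Sensitivity analysis.** For the test of one predictor in multiple
  regression with total sample n and c covariates, power is computed
  from the noncentral t distribution with df = n − c − 2 and
  noncentrality √(f²·n), f² = r²/(1 − r²); the minimum detectable |r|
  inverts this by Brent root finding (power(min r) = target to 1e-6,
  tested). One-sided tests use the upper-tail critical value; two-sided
  tests use |t|. Both c = 3 and c = 4 are supported (default 4). At the
  emulated design — n = 52, one-sided α = 0.05, power 0.8, 4
  covariates — the minimum detectable effect is r = 0.330, R² = 0.109.

## Pipeline

`run_pipeline` validates the config (collecting *all* schema and
cross-input errors: grid compatibility, EEG/hypnogram span, cohort
schema), then runs LC contrast → sleep metrics → cohort assembly →
statistics, writing CSV/JSON outputs with a fixed float format and a
manifest carrying the config hash, the seed and every design option in
effect (family, SWE stage set, FDR family, mediation reference rule).
Reruns with the same config are byte-identical; stage seeds are derived
from the global seed by fixed offsets. A failed stage aborts downstream
stages. Between-group protocol differences of the emulated design
(e.g. an EEG-to-MRI time gap in the older group) are representable only
as cohort metadata; no correction is attempted.

## Problem sizes used in the checks

The test suite and demo run at desk scale by design: phantom grids of
24 × 48 × 48 voxels, nights of 1–6 h at 200 Hz, cohorts of 52–2000
rows, 150–1000 simulation replicates, and 200–1000 bootstrap draws.
These sizes keep every calibration within tight Monte-Carlo error while
remaining quick on a single core.

## Known limitations

- EDF reading requires `mne`; there is no EDF writer (CSV is the
  native signal format).
- The reference-region placement is manual; no pons segmentation.
- Real-EEG artifacts are excluded by annotation only; no detector.
- The Gamma family covers right-skew, but no other GLM families are
  wired in.
- The mediation working models are linear; no exposure–covariate
  interactions or nonlinearity.
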