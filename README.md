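# lcsleep

Tools for studying how the **locus coeruleus (LC)** — the small pontine
nucleus that is the brain's main source of norepinephrine and a key
regulator of sleep–wake transitions — relates to the quality of human
sleep. The package reimplements, as a tested and reusable pipeline, the
quantitative chain linking three kinds of data:

1. **Neuromelanin-sensitive MRI** of the brainstem → a per-participant
   *LC contrast*, a proxy for LC structural integrity;
2. **Overnight sleep EEG** (hypnogram + frontal channel) → architecture
   metrics and cumulative spectral energies, notably slow wave energy
   (SWE) during slow wave sleep and cumulated theta power during REM
   sleep;
3. **A cohort table** (LC task-evoked activity, LC contrast, PSQI,
   demographics, sleep metrics) → moderated regression with per-group
   simple slopes, Benjamini–Hochberg FDR, counterfactual mediation, and
   an analytic sensitivity analysis.

Every stage has a synthetic counterpart with known ground truth
(`lcsleep.synthetic`), so the whole chain is testable without any data
download.

It is aimed at sleep/neuroimaging researchers who have per-participant
LC images and polysomnography and want a transparent, scriptable
alternative to the mix of MATLAB/SAS tooling such analyses usually
involve.

## The quantities at the core

**LC contrast.** The LC mask is *skeletonized*: in each axial slice `i`,
only the in-mask voxel with the highest intensity is kept, with
intensity `LC_i`. Each `LC_i` is normalized to the mean intensity of a
15 × 15-voxel square reference region in the pontine tegmentum of the
same slice:

```
contrast_i = (LC_i − mean(pons_i)) / mean(pons_i)
side contrast = mean_i contrast_i
bilateral contrast = (left + right) / 2
```

**Cumulative band energy.** Welch band power (4-s Hann segments, 2-s
overlap) is computed on segments free of annotated arousals/artifacts,
averaged per 30-min bin, weighted by the fraction of the bin spent in
the target stage (the adjustment for rejected data), and summed over
the night. SWE uses the 0.5–4 Hz band during N3; REM theta energy uses
4–8 Hz during REM.

**Statistics.** Each sleep outcome is modeled as
`outcome ~ LC_activity * age_group + sex + BMI (+ TST)` with per-group
simple slopes and partial R² = F/(F + df₂); the six primary interaction
p-values pass through BH-FDR at q = 0.05. Mediation uses the linear
counterfactual decomposition (controlled direct effect and pure
indirect effect as percentages of the total effect) with case-resampling
bootstrap. The sensitivity analysis inverts the noncentral-t power
function of one tested predictor in multiple regression.

## Worked example

The packaged demo generates all three inputs synthetically — a noisy LC
phantom with analytic contrast 0.2, a 2-h staged night at 200 Hz, and a
52-participant cohort (33 younger, 19 older) with an LC-activity ×
age-group interaction planted on PSQI and on REM theta energy — and runs
the full chain:

```bash
lcsleep run-all --demo --out demo_out --seed 7
```

Headline numbers from `demo_out` (your run reproduces them exactly —
the pipeline is a pure function of config and seed):

- `lc_contrast_summary.json`: left 0.1995, right 0.2008, bilateral
  **0.2001** against a ground truth of 0.2 — the skeleton + reference
  normalization recovers the phantom's analytic contrast through the
  noise.
- `sleep_metrics.json`: TST 110.5 min, sleep onset latency 5.0 min,
  efficiency 92.1 %, REM 21.7 %, SWE 123.1 µV², REM theta energy
  15.9 µV².
- `stats_report.json`: the interaction is detected on exactly the two
  planted outcomes — PSQI (p = 0.0025) and REM theta energy
  (p = 0.0135) — and both survive BH-FDR (critical p = 0.0135) while
  the four null outcomes do not. Simple slopes for PSQI: older group
  slope 1.29 (t = 3.81, p = 0.0004), younger group −0.06 (p = 0.80),
  i.e. higher LC activity predicts worse subjective sleep only in the
  older group, as planted. The exploratory mediation at n = 52 is
  flagged `unstable` (its bootstrap total-effect CI includes zero), so
  its effect percentages are reported but not interpretable.
- `sensitivity`: minimum detectable partial r = 0.330 (R² = 0.109) for
  one predictor with 4 covariates at n = 52, one-sided α = 0.05,
  power 0.8.

Each stage is also available separately (`lcsleep simulate`,
`lcsleep lc-contrast`, `lcsleep sleep-metrics`, `lcsleep associate`)
and as plain library calls; see the module docstrings.

## Cohort CSV schema

One row per participant:
`participant, age_group ∈ {young, old}, sex ∈ {F, M}, bmi, tst,
lc_activity, lc_contrast, psqi, sol, sleep_efficiency, rem_percentage,
swe, rem_theta_energy, rem_latency, rem_arousals, rem_episode_mean`.

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices, and what the synthetic generators do and do not
emulate.
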