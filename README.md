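# melrhythm

Modelling of the diurnal (circadian) blood melatonin rhythm from sparse
sampling profiles, with cohort-level statistics for comparing patient
groups — built for studies in which blood is drawn every 3 hours over a
single day (8–9 samples per subject) and the question is whether two
groups, e.g. children with and without epilepsy, differ in how and when
melatonin is released.

## The model

Each subject's concentration profile MLT(*t*) (pg/mL, *t* = clock time
in hours) is described by a 24-hour-periodic, bell-shaped curve with
four parameters:

```
MLT(t) = b1 + b2 · exp( −[ (cos(πt/12 − πb3/12) − 1) / s ]² )

s = (cos(πb4/24) − 1) / √(ln 2)
```

* **b1** — minimum (baseline) melatonin concentration [pg/mL]
* **b2** — release amplitude, peak minus baseline [pg/mL]
* **b3** — phase shift: the clock time of the nocturnal peak [h]
* **b4** — full width at half maximum of the peak, read as an estimate
  of sleep duration [h]

The maximum concentration is b<sub>max</sub> = b1 + b2, attained at
*t* = b3 (mod 24); the scale factor *s* makes the FWHM equal exactly b4.
Physiological ranges are enforced during fitting: b1, b2 ≥ 0,
b3 ∈ [0, 24), b4 ∈ (0, 12).

Per subject, the parameters are estimated by Levenberg–Marquardt
nonlinear least squares in a transformed, unconstrained space (log for
the concentrations, circular identity for the phase, scaled logistic
for the width). Fit quality is screened with the inclusion gates
explained variance > 90%, Pearson R(observed, fitted) > 0.95, residual
normality (Shapiro–Wilk, α = 0.05), and a bell-shape check; subjects
whose curve is not bell-shaped are excluded from all cohort statistics.
The cohort stage compares the fitted parameters between groups
(Mann–Whitney U), screens clinical covariates (Spearman rank
correlation; Pearson χ² for 2×2 tables) and regresses binary clinical
outcomes on (b1, b2, b3, b4) by logistic regression (b<sub>max</sub> is
omitted as it is the sum of b1 and b2).

A synthetic cohort generator reproduces the study structure end to end
— an epilepsy group (EG, n = 52) and a comparison group (CG, n = 30),
3-hourly sampling, multiplicative 5% assay noise, and clinical
covariates with configurable signed effects on the latent parameters —
so the whole pipeline is testable without any patient data.

## Worked example

```
$ melrhythm run --out demo --seed 1
analyzed 79/82 subjects (excluded 3); reports in demo

$ melrhythm compare --fits demo/fits.csv --clinical demo/clinical.csv --out demo
   b1: median EG     5.4039  CG     6.8514  p=0.0143*
   b2: median EG   116.2835  CG   135.4378  p=0.1094
   b3: median EG     2.2840  CG     1.6970  p=0.1007
   b4: median EG     7.1748  CG     7.1962  p=0.9155
b_max: median EG   121.0784  CG   143.1630  p=0.0714
excluded 3 subject(s)
```

`run` simulates a cohort under seed 1, fits every subject and writes
the reports. Three EG subjects were generated with deliberately
non-bell-shaped (flat or double-peaked) profiles; the quality gates
catch and exclude them. The table shows, per parameter, the group
medians of the fitted values and the two-sided Mann–Whitney p-value
(`*` marks p < 0.05). Medians land near the generator's configured
group centres (baseline ≈ 6 pg/mL, amplitudes ≈ 118 vs 143 pg/mL, peak
at ≈ 2.3 vs 1.5 h after midnight, width ≈ 7.2 h); whether a given
difference reaches significance at n = 52/30 varies seed to seed — the
phase-shift difference is detected in ≈ 96% of replicates, which the
test suite verifies.

Library use mirrors the CLI:

```python
import melrhythm as mr

profiles, records, truth = mr.generate_cohort(mr.GeneratorConfig(seed=1))
fit = mr.fit_profile(profiles[-1])
print(fit.params, fit.explained_variance, fit.quality_pass)

report = mr.run_end_to_end(mr.PipelineConfig(), "demo", seed=1)
```

Output tables (`profiles.csv`, `clinical.csv`, `fits.csv`,
`report_group.csv`, `report_corr_eg.csv`, `report_corr_cg.csv`,
`report_logit.csv`, `exclusions.csv`) are plain UTF-8 CSV with headers;
`manifest.json` records the full configuration and seed, and identical
configurations reproduce byte-identical outputs.

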