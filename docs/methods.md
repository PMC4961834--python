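# Methods

## The secretion model

The curve is built from a unit Gaussian whose argument is looped through
a cosine so that the function becomes exactly 24-hour periodic:

    MLT(t) = b1 + b2 · exp( −[ (cos(πt/12 − πb3/12) − 1) / s ]² ),
    s = (cos(πb4/24) − 1) / √(ln 2).

At the peak (t = b3) the cosine term vanishes and MLT = b1 + b2. At
t = b3 ± b4/2 the squared quotient equals ln 2, so the exponential is
exactly 1/2 — the FWHM of the peak is b4 by construction, which is what
fixes the form of s. The scale factor is negative for all admissible b4
(we keep that sign stable; it only ever enters squared). Over one
period the curve is unimodal: strictly decreasing on (b3, b3 + 12) and
strictly increasing on (b3 + 12, b3 + 24). Its minimum, at t = b3 + 12,
exceeds the baseline by b2·exp(−(2/s)²) — below 2.6% of the amplitude
for any b4 ≤ 11, and usually orders of magnitude less — so b1 is read
as "the minimum concentration". `min_concentration_gap` quantifies this
approximation, and `fwhm_numeric` re-measures the width by root
bracketing as a standing self-check of the construction.

Parameter ranges are physiological constraints, not conveniences:
b1, b2 ≥ 0 (concentrations), b3 ∈ [0, 24) (a clock time; the phase is
circular and values produced outside the range are wrapped modulo 24,
never rejected), b4 ∈ (0, 12) (a width narrower than half the period;
at b4 → 12 the scale factor degenerates and the curve loses its bell
shape). Time is clock time in hours after midnight; sampling times up
to 48 h are accepted and folded by periodicity. The anchor to midnight
places the fitted peaks at ~1.5–2.4 h, consistent with the
physiological nocturnal peak between 2 and 4 am.

## Fitting

Each subject is fitted independently (no pooling) by
Levenberg–Marquardt nonlinear least squares on the concentration
residuals. LM has no native box constraints, so the search runs in an
unconstrained internal space: u1 = ln b1, u2 = ln b2 (positivity),
u3 = b3 (wrapped mod 24 on output), u4 = logit(b4/12) (scaled logistic
onto (0, 12)). The damped Gauss–Newton loop uses Marquardt scaling of
the normal equations, a finite-difference Jacobian (central, relative
step 1e−6), step acceptance only on objective decrease (so the accepted
objective sequence is non-increasing), and per-component step clipping
at 10 internal units to keep the logistic transform out of its
saturated tails. Convergence is declared when the relative objective
reduction falls below `tol` (default 1e−10), the step norm falls below
1e−10, or no descent step exists at damping 1e14 (a stationary point);
the iteration cap is 200. If the default start does not converge,
deterministic restarts shift the initial phase by +3, −3, +6, −6 h —
3-hourly sampling can bracket the true peak between samples. A test
cross-checks converged solutions against an independent bounded
trust-region solver (scipy's TRF): restarting TRF from our solution
neither moves it nor improves the objective.

Starting values are moment-style: b1 = min sample, b2 = range,
b3 = time of the (earliest) maximum sample, b4 = linearly interpolated
width at half maximum around the peak, clipped to [0.5, 11.5]; a
constant profile short-circuits to b4 = 0.5 and zero amplitude.

Standard errors come from the Jacobian-based covariance at the optimum
in the original parameter space, σ²(JᵀJ)⁻¹ with σ² = SSE/(n − 4)
(pseudo-inverse for rank-deficient cases such as zero amplitude).

### Quality gates and exclusion

A fit enters cohort statistics only if its curve is bell-shaped; it is
additionally flagged `quality_pass` when explained variance
(1 − SS_res/SS_tot, floored at 0) exceeds 0.90, the Pearson correlation
between observed and fitted values exceeds 0.95, and a Shapiro–Wilk
test does not reject residual normality at α = 0.05 (chosen for the
very small residual samples, n = 8–9; residuals that are numerically
zero are treated as degenerate-pass). "Bell-shaped" is operationalized
as: the fit converged, the amplitude is Wald-significant (b2 ≥ 2 SE),
the amplitude is not negligible against the baseline (b2 ≥ 0.1·b1 —
"similar minimum and maximum" indicates absent release), and explained
variance exceeds 0.5. The thresholds in the bell-shape rule are package
choices; flat and double-peaked profiles fail it reliably, which the
tests exercise.

## Cohort statistics

All tests are two-sided at α = 0.05. Mann–Whitney U uses the exact
permutation null for tie-free samples with combined n ≤ 12 and the
tie- and continuity-corrected normal approximation otherwise (the
switchover point is a package convention; the corrected approximation
agrees with the exact enumeration within 0.03 in that range). Spearman
correlations use mid-ranks for ties and the t approximation with n − 2
degrees of freedom, adequate at group sizes of 30–52; an exact
permutation mode exists for tiny fixtures (n ≤ 8). The χ² test on 2×2
tables is Pearson's without continuity correction. Logistic regressions
of binary clinical outcomes on (b1, b2, b3, b4) are fitted by maximum
likelihood with Wald p-values, require at least 10 subjects per
predictor, and withhold coefficients when complete or quasi-separation
is detected (pinned fitted probabilities, runaway slopes, or exploded
standard errors). No multiple-testing correction is applied by default
— each table cell is flagged at its own 5% level; an optional Holm
adjustment can be switched on in the pipeline config. With four
independent 5%-level Wald tests per outcome, about 1 − 0.95⁴ ≈ 19% of
null cohorts will show at least one spuriously significant coefficient;
that is nominal behaviour, not miscalibration.

The compare stage consumes only fitted parameters and covariates, never
raw concentrations; per-subject b_max = b1 + b2 is computed before
ranking; disease-associated covariates are analyzed for the epilepsy
group only, and exclusion accounting (n_input = n_analyzed + n_excluded)
is enforced in every report.

## Synthetic cohort generator

The generator emulates the study design: 52 EG + 30 CG subjects,
8 samples at 0, 3, …, 21 h, and multiplicative Gaussian noise with
CV = 5% (a generic immunoassay error scale), floored at zero.
Parameters are drawn per subject — log-normal b1 and b2, wrapped-normal
b3, truncated-normal b4 on (0.5, 11.5) — with group medians at the
observed cohort values (b1: 5.99/6.46 pg/mL, b2: 117.9/142.8 pg/mL,
b3: 2.3851/1.4843 h, b4: 7.29/7.18 h for EG/CG). Age is matched across
groups (mean ≈ 6.8 y); EG covariates follow the reported clinical
ranges (1–4 drugs, 11–200 months duration, 1–42 h since last seizure).

Covariate effects act linearly on the latent scale (ln b2 or b3) with
covariates centered at their generative means, so they add association
without moving group medians. Signs follow the reported correlation
structure: amplitude falls with age (both groups) and disease duration,
and rises with seizure counts; the peak is delayed by seizure
frequency and drug count (EG) and by age (CG), and advanced by a long
seizure-free interval; baseline, width and the intellectual-development
quotient carry no effects (null rows). Magnitudes were sized once so
each configured effect contributes roughly 0.3–0.4 latent standard
deviations — large enough for its Spearman sign to reproduce in ≳95% of
cohorts at n = 52, small enough that the wrapped phase rarely crosses
midnight (≲2% of subjects per group). They are calibration knobs that
make the design's associations detectable at the study's sample sizes,
not estimates of real effect sizes. By default 5% of EG subjects get
non-bell-shaped profiles (alternating flat and double-peaked) to
exercise the exclusion path.

What the generator does *not* emulate: assay detection limits and
heteroscedastic error structure beyond a constant CV, correlations
among the seizure covariates (drawn independently), drug-specific
pharmacodynamics, and multi-day (≥ 48 h) recordings — the model itself
is restricted to a single 24-h period and would need extra parameters
for successive releases. Passing tests therefore demonstrate that the
pipeline recovers what this data-generating process encodes, not that
real cohorts satisfy the model.

## Problem sizes and numerical choices

The test suite uses 200 profiles for the noisy-recovery study, 2000
null replicates for rank-test calibration, and 100 cohort replicates
per arm for the phase-shift power analogue (observed power ≈ 0.96
against the configured 0.90 h group gap; nominal false positives under
the null configuration). The acceptance script scans candidate periods
on a 0.25 h grid over (0, 48] with a 1e−9 relative invariance
tolerance across 100 random parameter draws. Root bracketing for the
FWHM self-check uses Brent's method at xtol = 1e−12; dense-grid
oracles use steps of 1e−4 h or finer. Near its maximum the curve is
quadratically flat, so grid-argmax locates the peak only to ~1e−3 h in
double precision — tests compare accordingly.

## Known limitations

* Single daily release only; double releases and free-running
  (non-24 h) rhythms violate the model and are meant to be caught by
  the quality gates rather than fitted.
* The Shapiro–Wilk gate at n = 8 has little power and, conversely,
  flags ~5% of perfectly good fits; it is an inclusion screen, not a
  diagnosis.
* Phase comparisons near midnight are subject to wrapping: a cohort
  whose true peaks straddle t = 0 would need circular statistics,
  which the rank tests here do not provide.
* Standard errors are asymptotic (Jacobian-based) despite n = 8–9
  observations per subject; they are used for screening, not for
  per-subject confidence intervals.
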