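# Methods

`chronostab` implements two linked analyses of sleep timing, plus the
synthetic data needed to exercise them end to end.

## Mid-sleep scoring

Chronotype is operationalized as **mid-sleep**: the clock midpoint between
sleep onset and wake-up for one night, in decimal hours after midnight.
From diary items,

    sleep onset  = lights-off time + sleep latency
    duration     = wake-up time − sleep onset
    mid-sleep    = sleep onset + duration / 2.

Evening-side events are represented on a midnight-centered axis in
(−12, 12] (23:30 ↦ −0.5, 01:00 ↦ +1.0) and wake-side events on [0, 24).
Centering removes wrap-around arithmetic for sleepers on either side of
midnight; the convention is enforced at parse time and round-trips
losslessly with `"HH:MM"` text at minute resolution.

MCTQ (Munich Chronotype Questionnaire) records are scored the same way per
schedule, yielding MSW (mid-sleep on workdays) and MSF (mid-sleep on free
days). The sleep-debt-corrected variant uses the standard correction,
generalized to the respondent's reported workdays per week WD rather than a
fixed 5/2 split:

    SDweek = (WD·SDw + (7−WD)·SDf) / 7
    MSFsc  = MSF − (SDf − SDweek)/2   when SDf > SDw, else MSF.

Exclusion filtering is rule-based and fully logged. Because per-night
exclusion criteria in diary studies are often idiosyncratic, the package
ships configurable surrogates (duration outside [4 h, 16 h], latency
> 180 min, missing items; participant-level mean-duration and flag rules
for panels) and reports per-rule removal counts, so any filter choice is
reproducible and auditable.

## Variance decomposition (nightly diary data)

The model family is a Gaussian mixed model with one grouping factor
(participant). Two models are fitted per outcome (mid-sleep, sleep onset,
wake-up time):

1. **Intercept-only**: random intercepts, no fixed effects beyond the grand
   mean. The intraclass correlation ICC = σ²_b / (σ²_b + σ²_w) is the share
   of variance attributable to stable between-person differences; it is
   computed only for this model, where it is well defined.
2. **Day-type adjusted**: fixed effects for *workday today* (is the waking
   day a workday), *workday yesterday* (was the previous day one), and
   their interaction, with the maximal random structure — per-person
   intercepts and slopes for all three terms, correlated. Factors are
   sum-to-zero coded (+0.5 free day, −0.5 workday), so coefficients read as
   free-minus-work contrasts and the interaction is the product of the main
   columns. The headline quantity is the ratio σ²_w / σ²_b of the residual
   (within-person) variance to the random-intercept (between-person)
   variance. Slope variances are reported separately and deliberately
   excluded from the ratio, which reproduces the usual single-number
   "between" convention for such models.

The lagged factor is missing on first nights and after diary gaps; those
rows enter the intercept-only model but are dropped from any model using
the lag.

### REML engine

Variance components are estimated by restricted maximum likelihood,
implemented from scratch. The between covariance is parameterized by its
relative Cholesky factor Λ (Σ_b = σ²ΛΛ′), and β and σ² are profiled out, so
the numerical search runs only over Λ. Sufficient statistics (Z′Z, Z′X,
Z′y per participant) are precomputed once; a criterion evaluation costs
O(groups · q³) via batched Woodbury identities, independent of the number
of nights. The response is centered internally (and the shift restored on
the intercept), which makes the fit exactly equivariant to adding a
constant to the outcome.

Numerical choices:

* One free parameter (random intercept only): bounded golden-section/Brent
  search on [0, 10⁶] with a wide-step parabolic refinement that is robust
  to float-level noise in the profiled criterion, plus an explicit check of
  the boundary θ = 0.
* Several parameters: L-BFGS-B (diagonal entries bounded below by 0) from a
  method-of-moments start and 4 jittered copies (5 starts total), followed
  by a Nelder–Mead polish of the best candidate; convergence tolerance
  1e-8 on the deviance.
* **Singular-fit detection**: a fit is singular when any relative-Cholesky
  diagonal falls below 1e-4 (relative to the largest diagonal), any
  between-term correlation exceeds 0.9999 in magnitude, or the relative
  scale diverges (> 10⁴, the σ²_w → 0 boundary).
* **Simplification ladder**: the maximal model is fitted first; while the
  fit is singular, the next random term in the configured ladder
  (interaction slope, then the *yesterday* slope, then the *today* slope)
  is dropped and the model refitted. The fitted history is recorded.

Fixed effects carry Wald chi-square tests (1 df, asymptotic). These are
*not* Satterthwaite-approximate F tests: no denominator degrees of freedom
are approximated, which is adequate at this design's group counts and is
labeled accordingly. Tests are suppressed with a warning on singular fits,
where boundary estimates invalidate the asymptotics.

## Temporal stability (two-wave panel data)

Rank-order stability of MSF/MSW across two measurement waves is summarized
per participant by the Asendorpf individual-stability coefficient

    i12 = 1 − (z1 − z2)² / 2,

with z1, z2 the wave-wise standardized scores (full analysis sample, n−1
denominator). Its population mean equals the retest correlation r12. With
n−1 standardization the algebraically exact finite-sample identity is
1 − Σ(z1−z2)²/(2(n−1)) = r; the plain mean of i12 differs from r by
(1 − r)/n, which is negligible at panel sizes and is asserted at its exact
form in the tests. Because i12 is strongly left-skewed, analyses of its
age-dependence use the piecewise logarithmic transform

    T(i) = ½ ln[(1.001 + i)/(1.001 − i)]   for 0 ≤ i ≤ 1
    T(i) = ln[1/(1 − i)]                   for i < 0,

continuous at 0, strictly increasing, with T(1) ≈ 3.8 and T(0.99) ≈ 2.6.

Age-dependence is assessed three ways:

* **Stratified retest correlations** in fixed age groups (18–25, 26–35,
  36–45, 46–55, 56–65, 66–87 at T1) and retest-interval groups (0–1, 2, 3,
  4, 5 years; same-year completers are merged into the 1-year group because
  they are few).
* **Quadratic age curve**: OLS of T(i12) on age and age² (age uncentered so
  coefficients compare directly with printed curve equations; a centered
  fit is available for conditioning-sensitive uses). R² is reported
  unadjusted, for both the quadratic and the nested linear fit.
* **Hierarchical regression**: retest interval entered first, then age and
  age², with ΔR² and F-change tests per block and per-coefficient t tests.

Cross-method agreement (questionnaire recall vs diary averages vs
device-derived averages) uses Pearson correlations, and the free-vs-workday
comparison of two dependent, non-overlapping correlations uses Steiger's Z:
Fisher-transformed correlations with the Pearson–Filon covariance evaluated
at the pooled correlation. The literature offers several variants; this one
was chosen for its good type-I calibration, which the test suite verifies
by Monte-Carlo (2,000 null replicates).

## Synthetic data

The generators are first-class, tested code; they emulate the statistical
structure the analyses assume, not the physiology behind it.

**Diary generator.** Per participant, a latent chronotype c_i ~ N(μ, σ²_b);
per night, mid-sleep = c_i + day-type effects + N(0, σ²_w). Day-type
effects combine fixed free-vs-work shifts (waking day and previous day, on
±0.5 contrasts) with optional correlated per-person random slopes. Nightly
duration is drawn separately (person + night components); onset and wake
are back-computed, diary items snapped to whole minutes, and the recorded
truth re-derived from the snapped items, so scoring the emitted CSV
reproduces the generator's mid-sleep exactly (a round-trip the tests assert
at 1e-9 h). Work schedules default to a 5+2 weekly pattern with a
per-person phase; a Bernoulli alternative is available. Nights are dropped
independently at one minus the completion rate.

Defaults represent the experience-sampling regime this package targets:
111 participants (7 scheduled for 13 days, the rest 14), between-person SD
1.2 h, nightly SD 1.0 h, waking-day shift 0.5 h, previous-day shift
0.15 h, 87.98% completion, mean mid-sleep 5.0 h. The nightly SD is the
*residual* noise after day-type structure; with the default shifts the
intercept-only within-person SD comes out near 1.2 h, matching the regime
where the ICC is about one half.

**Recall generator.** MCTQ items are built from each participant's true
per-day-type diary means plus Gaussian recall noise; onset and wake receive
independent noise of SD √2·s so the implied mid-sleep recall error has SD
s. The induced questionnaire–diary correlation follows the attenuation
formula σ_b/√(σ_b² + s²), which the tests verify.

**Panel generator.** Ages are truncated-normal on 18–87 (mean 47.7, SD
15.9); retest intervals follow the observed group weights. Standardized T1
scores for MSF and MSW are correlated at 0.70; T2 scores are
ρ(age)·z1 + √(1−ρ(age)²)·ε with the T2 innovations sharing the same
cross-measure correlation, then rescaled to the configured means and SDs.
The stability curve ρ(age) is a clipped quadratic, specifiable on the
correlation scale or on the T scale (mapped back through the inverse
transform); the scale is part of the configuration. The default curve,
ρ = 0.75 − 0.0013(age−50)² (0.70 peak for MSW), is sharply peaked at 50:
it expresses a steep rise of stability from young adulthood to a middle-age
peak with later decline, strong enough that the age-group correlation
profile peaks in the 46–55 stratum in nearly every replicate at n = 681.
A flatter profile matching a full-sample retest correlation of ~0.66 is
obtained with the constant-curve configuration used in the tests for that
regime. Within-person nightly autocorrelation is not modeled (nights are
independent given day type), and no circadian physiology (light exposure,
melatonin) is simulated — so passing tests demonstrate correctness of the
estimators under the assumed structure, not robustness to serial
dependence or schedule feedback in real diaries.

## Problem sizes used by the test suite

The suites run the REML oracle comparisons on 20 unbalanced draws of 25–50
groups; parameter recovery on one 200 × 14 diary; the ladder study on 100
replicate diaries of 80 participants × 14 nights (slope SDs 0.6/0.5 h,
zero interaction-slope variance); the age-profile study on 100 replicate
panels of 681; and the null calibration of Steiger's Z on 2,000 replicates
of n = 120. These sizes were chosen so each statistical property is tested
at meaningful power on a single CPU.

## Known limitations

* One grouping factor only; no crossed or nested random effects, no
  non-Gaussian responses.
* No Satterthwaite or Kenward–Roger degrees of freedom; fixed-effect tests
  are asymptotic Wald chi-squares (or likelihood-ratio style comparisons at
  the user's discretion).
* With a truly zero variance component, REML legitimately returns a
  positive interior estimate in a substantial fraction of replicates (the
  boundary-hit probability of such estimators is well below 1 even
  asymptotically), so singular-fit-driven simplification is frequent but
  not near-certain; the ladder resolves the singular cases it is given in
  ≈95% of them with a single step.
* Raw actigraphy signal processing is out of scope; device-derived nightly
  times enter through the same diary schema.
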