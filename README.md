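# chronostab

Tools for studying **how stable a person's sleep timing is** — from night to
night, and over years.

Chronotype can be operationalized as *mid-sleep*: the clock midpoint between
sleep onset and wake-up, in hours after midnight (mid-sleep 5.0 ≈ 05:00).
`chronostab` is aimed at sleep and circadian researchers working with
sleep-diary (experience-sampling) data, Munich Chronotype Questionnaire
(MCTQ) data, or two-wave panel retests of either. It provides:

* **Scoring** — diary and MCTQ tables to mid-sleep variables
  (`mid_sleep = onset + duration/2`, with `onset = lights_off + latency`),
  including MSW/MSF and the sleep-debt-corrected MSFsc, on a
  midnight-centered time axis (23:30 ↦ −0.5 h); rule-based, fully logged
  exclusion filtering.
* **Variance decomposition** — a from-scratch REML mixed-model engine
  (random intercepts and correlated random slopes, one grouping factor)
  that splits nightly variance into within-person (σ²_w) and between-person
  (σ²_b) components, reports the intraclass correlation
  ICC = σ²_b/(σ²_b+σ²_w) for intercept-only models and the ratio σ²_w/σ²_b
  for models adjusting for free vs. workdays, and handles singular fits
  with a model-simplification ladder.
* **Temporal stability** — per-person Asendorpf stability coefficients
  i12 = 1 − (z1−z2)²/2 across two waves (population mean = retest
  correlation), their de-skewing t-transformation, age-stratified retest
  correlations, quadratic age curves, and hierarchical regressions;
  Steiger's Z for comparing dependent correlations across methods.
* **Synthetic data** — seeded diary, questionnaire-recall, and two-wave
  panel generators with the statistical structure the analyses assume, so
  the full pipeline runs without access-restricted cohort data.

## Worked example

```python
import numpy as np
from chronostab import (DiarySimConfig, simulate_diary, score_diary,
                        run_variability_study, PanelSimConfig, simulate_panel,
                        score_stability, quadratic_age_fit)

# --- nightly variance decomposition on a simulated 2-week diary ---------
sim = simulate_diary(DiarySimConfig(seed=3))
scored = score_diary(sim.diary)
icc_rep, adj_rep = run_variability_study(scored, "mid_sleep")
print(f"ICC = {icc_rep.icc:.3f}  "
      f"(between {icc_rep.var_between:.2f}, within {icc_rep.var_within:.2f})")
print(f"adjusted within/between ratio = {adj_rep.ratio_within_over_between:.2f}, "
      f"dropped random terms: {adj_rep.dropped_random_terms}")

# --- two-wave stability across age --------------------------------------
panel = simulate_panel(PanelSimConfig(seed=3))
scores = score_stability(panel, "msf")
quad = quadratic_age_fit(scores["t12"], scores["age_t1"])
print(f"stability peaks near age {quad.vertex_age:.0f} "
      f"(R² quadratic {quad.r2_quadratic_pct:.1f}%, linear {quad.r2_linear_pct:.1f}%)")
```

Output:

```
ICC = 0.551  (between 1.42, within 1.16)
adjusted within/between ratio = 0.65, dropped random terms: ['workday_today:workday_yesterday']
stability peaks near age 49 (R² quadratic 4.2%, linear 0.0%)
```

Read: about half of the nightly variance in mid-sleep reflects stable
between-person differences; once free-vs-workday structure is modeled, a
night fluctuates *less* within a person than chronotypes differ between
people (ratio 0.65). The maximal random-effects model was singular, and the
ladder removed exactly the interaction slope. In the panel, rank-order
stability of mid-sleep on free days rises from young adulthood and peaks
near age 50.

A CLI mirrors the library (`chronostab simulate-diary | simulate-panel |
score-mctq | fit-variability | fit-stability | report`); all tabular I/O is
CSV, summaries are JSON, and every output directory gets a metadata sidecar
(config hash, seed, version) so reruns are byte-identical.

See `docs/methods.md` for the model details, estimator internals, generator
calibration, and known limitations.

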