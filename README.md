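# nuage

Measurement-error and seasonality correction for diet-adherence indices
in multicenter dietary intervention trials.

## The problem

Two-visit intervention trials often score diet adherence with an index
computed from a 7-day food record — one noisy snapshot of habitual
intake per visit. Two distortions follow if the noise is ignored:

* **Regression to the mean.** Measurement noise induces a spurious
  negative correlation between the baseline score and the observed
  change, and inflates the apparent spread of the intervention effect.
  When the within-subject (measurement) SD is comparable to the
  between-subject spread, the effective variance of the data doubles —
  equivalent to halving the sample size.
* **Seasonality.** Diets drift over the year. When visits are not
  exactly a year apart and recruitment is spread over the calendar,
  a yearly oscillation of the index contaminates both the baseline and
  the change.

This package targets a 0–160 adherence index (the sum of sixteen 0–10
continuous component scores, as used in a five-country Mediterranean-
style intervention in older adults) but every scale, cutoff and cohort
layout is configuration.

## What it does

For a cohort with subjects *i* nested in countries *c*, arms
(control/intervention) and visits T0/T1 at year fractions *t*:

```
y_i0 = b_i + season_c(t_i0) + e_i0
y_i1 = b_i + s_i d_i + season_c(t_i1) + e_i1

b_i ~ N(B_c, σ_between)       subject true baseline
d_i ~ N(D_c, σ_effect)        subject response; D_c ~ N(D, σ_country)
e   ~ N(0, σ_meas)            measurement noise per visit
season_c(t) = w_sin,c sin 2πt + w_cos,c cos 2πt   (weights pooled
              hierarchically around shared weights)
```

with `s_i = 1` for intervention and a small participation-drift
fraction (default 0.05) for controls. Because every subject-level
quantity is Gaussian, `b_i` and `d_i` are marginalized analytically and
only the hyperparameters are sampled (ensemble MCMC, non-centered
hierarchies); corrected per-subject scores are recovered by exact
Gaussian conditioning within each posterior draw.

Modules:

* `nuage.cohort` — synthetic multi-country two-visit cohort generator
  with ground truth (defaults emulate a 1,133-subject, five-country,
  two-arm study with ≈80-point baselines, a 20-point intervention
  effect — nearly double in one outlier country — and country-level
  yearly seasonality).
* `nuage.rtm` — the regression-to-the-mean null model: closed-form and
  Monte-Carlo curves mapping the within/between variability ratio
  λ = σ_meas/σ_between to the expected difference–baseline correlation,
  plus inversion of an observed correlation into λ with an IQR.
* `nuage.index` — config-driven continuous component scorer (adequacy /
  limit / range components, per-country percentile caps, exclusion
  filters).
* `nuage.model` — the hierarchical Bayesian fit, posterior summaries
  (means, 50%/95% HDIs, per-repeat means, R̂/ESS), variance components,
  per-country seasonality estimates and shrinkage-corrected scores.
* `nuage.pipeline` / `nuage.cli` — end-to-end orchestration and the
  `nuage` command (`simulate`, `score`, `rtm`, `fit`, `report`, `all`).

## Worked example

```python
import numpy as np
from nuage import cohort, model, rtm

records, truth = cohort.generate_cohort(cohort.default_config(seed=1))

print(rtm.regression_to_mean_table(records).round(2).to_string(index=False))
curve = rtm.simulate_null(rtm.NullModelConfig(seed=1))
est = rtm.invert_curve(curve, -0.473)   # the diet-arm correlation below

inputs = model.build_inputs(records)
fit = model.fit_model(inputs, model.ModelSpec(n_repeats=2, chains=2, seed=2))
var = model.variance_ratio(fit)
scores = model.correct_scores(fit)
```

prints (about a minute on one CPU):

```
         arm   n  mean_difference  difference_sd  diff_t0_r
     control 568             0.38          23.53      -0.48
intervention 565            21.69          24.26      -0.47
observed diet-arm r = -0.473 -> lambda = 1.21, IQR [1.17, 1.26]
posterior lambda median = 1.03, IQR [1.00, 1.06], 95% [0.95, 1.11]
effect France: 37.9
effect Italy: 22.3
effect Netherlands: 17.1
effect Poland: 16.5
effect United Kingdom: 18.2
control |T1-T0|: raw 18.9 -> corrected 1.1 points
```

Reading this: the strong negative difference–baseline correlations
(≈ −0.47) in both arms are the regression-to-the-mean signature; the
null model converts them into a within/between ratio above 1, and the
full hierarchical fit recovers the generating ratio (1.03) with a tight
interval. Country intervention effects are recovered near the
generating 20 points (38 for the outlier country), and the corrected
control scores collapse onto the identity line (mean |T1−T0| drops from
18.9 to 1.1 points) because the apparent change in controls was almost
entirely measurement noise and seasonality.

The same run from the shell:

```
nuage all --seed 1 --out-dir outputs/
```

writes `cohort.csv`, `arm_summary.csv`, `inversion.csv`,
`posterior_summary.csv`, `corrected_scores.csv`, `seasonality.csv` and
a `report.json` with seeds, runtimes, diagnostics and checksums.

## Limitations

See `docs/methods.md` for the model's assumptions, prior choices,
sampler details and known limitations (notably the attenuation of
per-country seasonal amplitudes by partial pooling at realistic noise
levels, and the variant ambiguity of the null-model inversion).
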