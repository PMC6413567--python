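# Methods

## Scope and model

The package corrects a two-visit diet-adherence index (0–160 points,
the sum of sixteen 0–10 component scores) for measurement error and
seasonality in a multi-country two-arm trial. The observation model is

    y_i0 = b_i + season_c(t_i0) + e_i0
    y_i1 = b_i + s_i·d_i + season_c(t_i1) + e_i1

* `b_i ~ N(B_c, σ_between)` — subject true baseline around a country
  center. The country centers get independent weakly-informative priors
  (a single-layer hierarchy): one country in a realistic cohort can be
  a baseline outlier, and forcing a common hyper-level on five centers
  buys little while hurting convergence.
* `d_i ~ N(D_c, σ_effect)`, `D_c ~ N(D, σ_country)` — a two-layer
  hierarchy for the intervention effect (subject within country within
  a global effect). An optional Student-t (df 4) country-effect
  distribution is exposed as an outlier-robustness toggle, off by
  default.
* `s_i` is 1 for the intervention arm and `control_drift` (default
  0.05, the participation effect as a fraction of the country effect)
  for controls. The stable-controls assumption is what identifies
  σ_meas. The drift can alternatively be estimated under a tight
  prior (`estimate_control_drift`).
* `season_c(t) = w_sin,c sin(2πt) + w_cos,c cos(2πt)` — one yearly
  harmonic per country, additive on the index scale, zero-mean over the
  year. Country weights are pooled around shared weights with a learned
  spread τ. Seasonality is a country-level effect: with two visits per
  subject an individual seasonal effect is not identifiable.
* `e ~ N(0, σ_meas)` i.i.d. — the Gaussian likelihood is justified by
  the index being a sum of 16 bounded components.

Dates enter as year fractions, `(day_of_year − 1)/365.25`, half-open
on [0, 1).

## Priors (all exposed in `ModelSpec`)

Weakly informative on the 0–160 scale: `B_c ~ N(80, 20)`;
`D ~ N(0, 20)`; all SDs half-Normal(0, 20); shared seasonal weights
`N(0, 5)`; τ half-Normal(0, 5). These are reconstructions chosen once
on scale arguments — the analysis is likelihood-dominated at n ≈ 1,000
for everything except the seasonal block (see Limitations).

## Inference

Every subject-level quantity is Gaussian, so `b_i` and `d_i` are
marginalized analytically: given the hyperparameters each subject's
visit pair is bivariate normal with covariance

    [[vb + vm,  vb            ],
     [vb,       vb + s²ve + vm]]

(`vb, vm, ve` squared SDs). The remaining ~28-dimensional
hyperparameter posterior is sampled with emcee's ensemble sampler
(80% differential-evolution + 20% snooker moves, 64 walkers).
Hierarchical levels use non-centered offsets (`value = mean + scale·z`,
`z ~ N(0,1)`), which removes the funnel between group scales and group
values. Collapsing the ~2,300 latent subject parameters rather than
sampling them is both faster and better-mixing; per-subject posteriors
are recovered exactly afterwards by Gaussian conditioning within each
draw (a Rao-Blackwellized estimate).

Sampler defaults: 2 chains per repeat, 1,500 warmup steps, 1,000
retained steps thinned to 1,000 draws per chain, 5 independent repeats
(the per-repeat means are reported separately as a stability display;
2 repeats suffice for point estimates). Diagnostics: split-chain R̂ and
ESS via arviz over repeats × chains, plus the ensemble acceptance
fraction. R̂ above 1.01 attaches a flag to the result and warns — at
the default budget the worst R̂ is typically 1.02–1.04, so the flag
fires as an honest marginal-convergence signal; quadrupling the steps
brings it under 1.02. HDIs are contiguous minimal-width intervals;
multimodal posteriors are still summarized by one interval.

Corrected scores: corrected T0 = E[b_i | data] and corrected
T1 = E[b_i + s_i d_i | data], averaged over draws; seasonal terms are
excluded from both, so corrected values are season-free (re-adding a
reference-season value would be a display choice, not a model one).
Posterior SDs combine within-draw conditional variance and between-draw
spread (law of total variance). At a fixed parameter point the
conditional mean of `b_i` is a convex combination of the country
center, the season-adjusted T0 score and the season-and-effect-adjusted
T1 score — the partial-pooling "betweenness" property, exposed for
testing via `conditional_truth_given`.

## The null model

The regression-to-the-mean sanity check simulates idealized paired
measurements: baselines N(0,1), optionally a true between-visit change
N(0,1), and measurement noise N(0,λ) at each visit. Closed forms:

    r(λ) = −λ² / sqrt((1+λ²)(1+2λ²))   with the change term
    r(λ) = −λ  / sqrt(2(1+λ²))          without it

both 0 at λ=0 and → −1/√2 ≈ −0.707 as λ → ∞. Inversion interpolates
the (monotone-enforced) Monte-Carlo mean curve; the IQR comes from
inverting each per-rep curve realization; degenerate grid points (λ=0
without the change term has an identically zero difference) are
dropped. The two variants bracket reality whenever the true
between-visit variability is positive but smaller than the
between-subject spread — which is the generator's regime
(σ_effect = 5 vs σ_between ≈ 15.5) — so compatibility between the null
model and the full fit is assessed as bracketing, not as agreement with
either single variant.

## The synthetic cohort generator

Defaults emulate a five-country cohort of 1,133 subjects
(241/251/235/222/184 for Italy / UK / Netherlands / Poland / France),
balanced arms within country, T0 uniform over the year, T1 = T0 plus a
uniform 10–14-month gap. Generating values: baselines 80 points
(Netherlands 87 — the baseline-outlier direction is a convention, the
magnitude matches the 6–8-point between-country differences the model
is meant to resolve); intervention effect 20 points except France
(38, the effect outlier); σ_meas = 16 (20% of the baseline, the
typical short-term food-record variability in older adults);
σ_between = 16/1.03 (within/between ratio 1.03); σ_effect = 5 (≈25% of
the effect — neither the cohort description nor the index literature
pins this, it is chosen once as realistic); control drift 5% of the
country effect. Seasonal peak-to-trough: 4 points for France and
Poland, 2.5 for Italy, 1 for UK and Netherlands, peaking near mid-year
(peak fractions 0.45/0.55/0.50/0.35/0.65 — a convention; only
amplitudes are scientifically constrained). Observed scores are NOT
clipped to [0, 160]: the likelihood is Normal and clipping would bias
the variance components.

What the generator does not emulate: individual food diaries, energy
trajectories, dropout, non-Gaussian index noise, learning effects in
record-keeping, or individual-level seasonality. Passing recovery
tests therefore shows the estimator is correct under its own
assumptions, not that real food-record noise is Gaussian.

## The component scorer

Piecewise-linear continuous scoring between a 0-point and a 10-point
cutoff per component; `adequacy` ramps up, `limit` ramps down, `range`
scores 10 inside a band with linear ramps outside. Percentile caps
(e.g. 85th for sodium/sweets, 100th for whole grains/low-fat meat) are
resolved per country with the linear-interpolation empirical quantile —
at small n the quantile method visibly moves the cap, which is why it
is fixed and documented. Exclusions (in fixed order: incomplete diary,
missing supplement data, energy < 500 kcal, energy > 3,500 kcal) use
strict inequalities, so boundary energies are kept. The shipped
16-component spec file is illustrative: real guideline cutoffs are
study-specific configuration.

## Numerical choices

* Log-parametrized SDs with Jacobian-corrected half-Normal priors.
* Data-driven sampler initialization (country means, control-arm
  covariance for vb/vm) with small jitter; walkers start tight around
  it.
* Inversion ties resolve toward the smaller λ; observed correlations
  at or beyond −1/√2 raise (no λ attains them).
* `fix={"sigma_meas": ...}` pins a variance component (the coordinate
  becomes a dummy), used for zero-noise degenerate checks.
* Seasonal peak fraction is the circular mean direction of the weight
  draws, `atan2(E ws, E wc)/2π mod 1`.

## Known limitations

* **Seasonal amplitude attenuation.** At the default noise level the
  per-country weight likelihood SE is ≈1.3 points while the largest
  generating amplitude is 2.0 — a ~1.5σ signal. Adaptive pooling
  therefore shrinks per-country amplitudes toward the shared weights:
  the posterior-mean peak-to-trough for a generating 4 points typically
  lands between 2.4 and 4.7 depending on the cohort realization, and a
  zero-seasonality cohort shows a noise floor of 1–2.5 points rather
  than zero (chance date–baseline correlation). In a lower-noise regime
  the amplitude posterior separates cleanly (tested). Unpooled weights
  would center the estimate higher but roughly double its spread and
  lose the zero-amplitude concentration.
* **Null-model inversion variant ambiguity.** An observed correlation
  maps to different λ under the with-/without-change variants (e.g.
  −0.49 → ≈1.29 vs ≈0.96); when the true change variability is between
  zero and the baseline spread, the right answer is between them. Both
  variants are exposed; single-number inversions should be read with
  that bracket in mind.
* The control-drift fraction is assumed known (or tightly prior-bound);
  a freely estimated drift is confounded with the control-arm seasonal
  difference.
* Country-level seasonality only; intermediate visits are out of scope.
* HDIs are forced contiguous; a genuinely multimodal posterior would be
  summarized too narrowly.
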