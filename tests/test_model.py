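import dataclasses

import numpy as np
import pytest

from conftest import quick_model_spec, scaled_countries
from nuage import cohort, model
from nuage.exceptions import InputError


def _toy_records():
    return [
        cohort.VisitRecord("a", "Italy", "control", "T0", 0.0, 80.0),
        cohort.VisitRecord("a", "Italy", "control", "T1", 0.1, 81.0),
        cohort.VisitRecord("b", "France", "intervention", "T0", 0.5, 70.0),
        cohort.VisitRecord("b", "France", "intervention", "T1", 0.6, 95.0),
    ]


class TestBuildInputs:
    def test_two_subjects_two_visits(self):
        inputs = model.build_inputs(_toy_records())
        assert inputs.n_subjects == 2
        assert inputs.n_countries == 2
        assert len(np.concatenate([inputs.y0, inputs.y1])) == 4
        assert inputs.country_names[inputs.country_idx[0]] == inputs.countries[0]

    def test_day_of_year_to_fraction(self):
        assert model.day_of_year_to_fraction(1) == 0.0
        assert model.day_of_year_to_fraction(183) == pytest.approx(0.498, abs=0.001)

    def test_missing_visit_names_subject(self):
        with pytest.raises(InputError, match="b"):
            model.build_inputs(_toy_records()[:3])

    def test_duplicated_visit_rejected(self):
        records = _toy_records() + [
            cohort.VisitRecord("a", "Italy", "control", "T0", 0.2, 82.0)
        ]
        with pytest.raises(InputError, match="duplicated"):
            model.build_inputs(records)

    def test_unknown_arm_rejected(self):
        records = [
            cohort.VisitRecord("a", "Italy", "placebo", "T0", 0.0, 80.0),
        ]
        with pytest.raises(InputError, match="arm"):
            model.build_inputs(records)


class TestHdi:
    def test_point_mass(self):
        lo, hi = model.hdi(np.full(500, 3.25), 0.95)
        assert (lo, hi) == (3.25, 3.25)

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(100_000)
        lo, hi = model.hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_hdi_is_shortest_interval_on_skewed_sample(self):
        # for a skewed distribution the HDI is shorter than the central interval
        rng = np.random.default_rng(1)
        draws = rng.exponential(1.0, 50_000)
        lo, hi = model.hdi(draws, 0.9)
        central = np.percentile(draws, [5, 95])
        assert hi - lo < central[1] - central[0]
        assert lo == pytest.approx(0.0, abs=0.01)


class TestFitRecovery:
    def test_posterior_tracks_truth_on_small_cohort(self, small_cohort, small_fit):
        cfg, _, truths = small_cohort
        names = small_fit.country_names
        d_post = small_fit.flat("D_c").mean(axis=0)
        by_country = {c.name: c.effect_mean for c in cfg.countries}
        for i, name in enumerate(names):
            # per-country effect SE at n=100/country is ~2.3; allow 3 SE + shrinkage
            assert d_post[i] == pytest.approx(by_country[name], abs=8.0)
        lam = np.median(small_fit.flat("lambda_ratio"))
        assert lam == pytest.approx(1.03, abs=0.25)

    def test_variance_ratio_scales_with_generating_noise(self):
        # doubling sigma_meas roughly doubles the recovered ratio
        medians = []
        for sigma_meas, seed in ((8.0, 3), (16.0, 3)):
            cfg = cohort.CohortConfig(
                countries=scaled_countries(120, zero_season=True),
                sigma_meas=sigma_meas,
                seed=seed,
            )
            records, _ = cohort.generate_cohort(cfg)
            fit = model.fit_model(
                model.build_inputs(records),
                quick_model_spec(warmup=500, steps=250, draws=300, seed=4),
            )
            medians.append(np.median(fit.flat("lambda_ratio")))
        assert medians[1] / medians[0] == pytest.approx(2.0, rel=0.25)

    def test_zero_noise_recovers_baselines_exactly(self):
        countries = scaled_countries(60, zero_season=True)
        cfg = cohort.CohortConfig(countries=countries, sigma_meas=0.0, seed=5)
        records, truths = cohort.generate_cohort(cfg)
        fit = model.fit_model(
            model.build_inputs(records),
            quick_model_spec(
                warmup=500, steps=250, draws=300, seed=7, fix={"sigma_meas": 0.05}
            ),
        )
        corrected = model.correct_scores(fit).set_index("subject_id")
        truth = cohort.truth_to_frame(truths).set_index("subject_id")
        err = (corrected["corrected_t0"] - truth["true_baseline"]).abs()
        assert err.max() < 0.1


class TestSummaries:
    def test_summary_intervals_are_nested_and_contain_mean(self, small_fit):
        summaries, var, seas = model.summarize_posterior(small_fit)
        for s in summaries:
            assert s.hdi95[0] <= s.hdi50[0] <= s.hdi50[1] <= s.hdi95[1]
            assert s.hdi95[0] <= s.mean <= s.hdi95[1]
        assert var.lambda_iqr[0] <= var.lambda_median <= var.lambda_iqr[1]
        assert var.lambda_95[0] <= var.lambda_iqr[0]
        for est in seas:
            assert est.amplitude_mean >= 0.0
            assert 0.0 <= est.peak_fraction < 1.0
            assert est.peak_to_trough_mean == pytest.approx(2 * est.amplitude_mean)

    def test_lambda_consistent_with_components_drawwise(self, small_fit):
        var = model.variance_ratio(small_fit)
        np.testing.assert_allclose(
            var.lambda_ratio, var.sigma_meas / var.sigma_between
        )

    def test_peak_fraction_of_pure_cosine_is_january(self):
        ws = np.random.default_rng(0).normal(0.0, 0.01, 1000)
        wc = np.abs(np.random.default_rng(1).normal(3.0, 0.01, 1000))
        est = model._seasonality_from_draws(ws, wc, "X")
        circular_distance = min(est.peak_fraction, 1.0 - est.peak_fraction)
        assert circular_distance == pytest.approx(0.0, abs=0.01)

    def test_too_few_draws_rejected(self, small_fit):
        tiny = dataclasses.replace(small_fit)
        tiny.draws = {k: v[:, :, :10] for k, v in small_fit.draws.items()}
        with pytest.raises(InputError, match="few"):
            model.summarize_posterior(tiny)


class TestCorrectScores:
    def test_controls_converge_toward_identity(self, small_fit):
        cs = model.correct_scores(small_fit)
        ctrl = cs[cs.arm == "control"]
        raw = (ctrl.raw_t1 - ctrl.raw_t0).abs().mean()
        corrected = (ctrl.corrected_t1 - ctrl.corrected_t0).abs().mean()
        assert corrected < raw

    def test_intervention_converges_toward_offset_line(self, small_fit):
        cs = model.correct_scores(small_fit)
        iv = cs[cs.arm == "intervention"].copy()
        d_post = {
            name: small_fit.flat("D_c")[:, i].mean()
            for i, name in enumerate(small_fit.country_names)
        }
        offset = iv.country.map(d_post)
        raw = (iv.raw_t1 - iv.raw_t0 - offset).abs().mean()
        corrected = (iv.corrected_t1 - iv.corrected_t0 - offset).abs().mean()
        assert corrected < raw

    def test_shrinkage_is_convex_combination(self, small_fit):
        # At any fixed parameter point the conditional mean of the true
        # baseline is a convex combination of the country center, the
        # season-adjusted T0 score and the season-and-effect-adjusted T1
        # score — so it lies inside their convex hull, for every subject.
        fit = small_fit
        inp = fit.inputs
        theta = {
            name: fit.flat(name).mean(axis=0)
            for name in ("B_c", "D_c", "w_sin", "w_cos")
        }
        for name in ("sigma_meas", "sigma_between", "sigma_effect", "drift"):
            theta[name] = float(fit.flat(name).mean())
        eb, _, _, _ = model.conditional_truth_given(theta, inp)
        ci = inp.country_idx
        s = np.where(inp.is_control, theta["drift"], 1.0)
        season0 = theta["w_sin"][ci] * np.sin(2 * np.pi * inp.t0) + theta["w_cos"][
            ci
        ] * np.cos(2 * np.pi * inp.t0)
        season1 = theta["w_sin"][ci] * np.sin(2 * np.pi * inp.t1) + theta["w_cos"][
            ci
        ] * np.cos(2 * np.pi * inp.t1)
        z0 = inp.y0 - season0
        z1 = inp.y1 - season1 - s * theta["D_c"][ci]
        lo = np.minimum.reduce([theta["B_c"][ci], z0, z1])
        hi = np.maximum.reduce([theta["B_c"][ci], z0, z1])
        assert np.all(eb >= lo - 1e-8) and np.all(eb <= hi + 1e-8)

    def test_posterior_sds_positive_and_below_measurement_sd(self, small_fit):
        cs = model.correct_scores(small_fit)
        sigma_meas = small_fit.flat("sigma_meas").mean()
        assert (cs.sd_t0 > 0).all()
        assert (cs.sd_t0 < sigma_meas).all()


def test_fit_determinism_same_seed(small_cohort):
    _, records, _ = small_cohort
    inputs = model.build_inputs(records)
    spec = quick_model_spec(warmup=150, steps=80, draws=100, seed=9)
    f1 = model.fit_model(inputs, spec)
    f2 = model.fit_model(inputs, spec)
    np.testing.assert_array_equal(f1.flat("D"), f2.flat("D"))
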