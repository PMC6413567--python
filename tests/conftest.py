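import dataclasses

import pytest

from nuage import cohort, model


def scaled_countries(n_per_country: int, zero_season: bool = False):
    """Default five-country configuration scaled to n subjects per country."""
    out = []
    for c in cohort.default_countries():
        c = dataclasses.replace(c, n_subjects=n_per_country)
        if zero_season:
            c = dataclasses.replace(
                c, seasonal_weight_sin=0.0, seasonal_weight_cos=0.0
            )
        out.append(c)
    return out


def quick_model_spec(**overrides) -> model.ModelSpec:
    """Short-chain sampler settings for test-scale fits."""
    defaults = dict(n_repeats=1, chains=2, warmup=700, steps=350, draws=400, seed=0)
    defaults.update(overrides)
    return model.ModelSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced study-like cohort (100 subjects/country), with truth."""
    cfg = cohort.CohortConfig(countries=scaled_countries(100), seed=5)
    records, truths = cohort.generate_cohort(cfg)
    return cfg, records, truths


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """One short fit of the reduced cohort, shared across tests."""
    _, records, _ = small_cohort
    inputs = model.build_inputs(records)
    return model.fit_model(inputs, quick_model_spec(seed=6))
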