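import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nuage import index
from nuage.exceptions import ConfigurationError, InputError

ADEQ = index.ComponentSpec("fruits", "adequacy", full_score_cutoff=200.0, zero_score_cutoff=0.0)
LIMIT = index.ComponentSpec("sweets", "limit", full_score_cutoff=25.0, zero_score_cutoff=75.0)
RANGE = index.ComponentSpec(
    "eggs",
    "range",
    zero_score_cutoff=0.0,
    full_score_cutoff=2.0,
    full_score_cutoff_high=4.0,
    zero_score_cutoff_high=7.0,
)


class TestScoreComponent:
    @pytest.mark.parametrize(
        "spec, intake, expected",
        [
            (ADEQ, 200.0, 10.0),  # at the full-score cutoff
            (ADEQ, 100.0, 5.0),  # linear midpoint
            (ADEQ, 500.0, 10.0),  # clamped above
            (ADEQ, 0.0, 0.0),
            (LIMIT, 0.0, 10.0),  # lower intake of a limit component scores full
            (LIMIT, 75.0, 0.0),
            (LIMIT, 50.0, 5.0),
            (RANGE, 3.0, 10.0),  # inside the band
            (RANGE, 1.0, 5.0),  # lower ramp midpoint
            (RANGE, 5.5, 5.0),  # upper ramp midpoint
            (RANGE, 10.0, 0.0),
        ],
    )
    def test_piecewise_linear_values(self, spec, intake, expected):
        assert index.score_component(intake, spec) == pytest.approx(expected)

    def test_negative_intake_rejected(self):
        with pytest.raises(InputError):
            index.score_component(-1.0, ADEQ)

    @given(st.floats(0, 400), st.floats(0, 400))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_stated_direction(self, a, b):
        lo, hi = sorted((a, b))
        assert index.score_component(lo, ADEQ) <= index.score_component(hi, ADEQ)
        assert index.score_component(lo, LIMIT) >= index.score_component(hi, LIMIT)

    def test_invalid_cutoff_ordering_rejected(self):
        with pytest.raises(ConfigurationError):
            index.ComponentSpec("x", "adequacy", full_score_cutoff=1.0, zero_score_cutoff=2.0)


class TestComputeIndex:
    def test_bounds_and_sum(self):
        assert index.compute_index([10.0] * 16) == 160.0
        assert index.compute_index([0.0] * 16) == 0.0
        assert index.compute_index([10.0] * 8 + [0.0] * 8) == 80.0

    def test_wrong_count_rejected(self):
        with pytest.raises(InputError):
            index.compute_index([10.0] * 15)

    @given(st.lists(st.floats(0, 10), min_size=16, max_size=16), st.randoms())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_invariance(self, scores, rnd):
        shuffled = list(scores)
        rnd.shuffle(shuffled)
        assert index.compute_index(scores) == pytest.approx(index.compute_index(shuffled))

    @given(
        st.lists(st.floats(0, 10), min_size=16, max_size=16),
        st.integers(0, 15),
        st.floats(0, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_lipschitz_in_each_component(self, scores, pos, new_value):
        perturbed = list(scores)
        perturbed[pos] = new_value
        delta = abs(index.compute_index(scores) - index.compute_index(perturbed))
        assert delta <= abs(scores[pos] - new_value) + 1e-9


class TestDeriveCaps:
    def _records(self, values, component="sweets", country="Italy"):
        return [
            index.IntakeRecord(f"S{i}", country, {component: v})
            for i, v in enumerate(values)
        ]

    def test_percentile_100_is_maximum(self):
        spec = index.ComponentSpec(
            "sweets", "limit", 0.5, 10.0, cap_rule=index.CapRule(100.0)
        )
        (updated,) = index.derive_caps(self._records([1.0, 2.0, 3.0]), [spec])
        assert updated.zero_score_cutoff == pytest.approx(3.0)

    def test_percentile_85_matches_empirical_quantile(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, 100)
        spec = index.ComponentSpec(
            "sweets", "limit", 1e-6, 10.0, cap_rule=index.CapRule(85.0)
        )
        (updated,) = index.derive_caps(self._records(values), [spec])
        assert updated.zero_score_cutoff == pytest.approx(
            np.quantile(values, 0.85), abs=1e-9
        )
        assert updated.zero_score_cutoff == pytest.approx(0.85, abs=0.1)

    def test_no_cap_rule_passes_through(self):
        specs = index.derive_caps(self._records([1.0]), [LIMIT])
        assert specs == [LIMIT]

    def test_empty_stratum_raises_with_name(self):
        spec = index.ComponentSpec(
            "sweets", "limit", 0.5, 10.0, cap_rule=index.CapRule(85.0)
        )
        records = [index.IntakeRecord("S1", "Italy", {"fruits": 1.0})]
        with pytest.raises(InputError, match="sweets"):
            index.derive_caps(records, [spec])


class TestApplyExclusions:
    @pytest.mark.parametrize(
        "record, reason",
        [
            (index.IntakeRecord("a", "IT", energy_kcal=400.0), "low-energy"),
            (index.IntakeRecord("b", "IT", energy_kcal=3600.0), "high-energy"),
            (index.IntakeRecord("c", "IT", complete=False), "incomplete-diary"),
            (
                index.IntakeRecord("d", "IT", supplement_data_present=False),
                "missing-supplement-data",
            ),
        ],
    )
    def test_exclusion_reasons(self, record, reason):
        kept, excluded = index.apply_exclusions([record])
        assert kept == [] and excluded == [(record, reason)]

    def test_boundary_energies_kept(self):
        records = [
            index.IntakeRecord("a", "IT", energy_kcal=500.0),
            index.IntakeRecord("b", "IT", energy_kcal=3500.0),
            index.IntakeRecord("c", "IT", energy_kcal=2000.0),
        ]
        kept, excluded = index.apply_exclusions(records)
        assert kept == records and excluded == []

    def test_partition_is_exact(self):
        rng = np.random.default_rng(1)
        records = [
            index.IntakeRecord(
                f"s{i}",
                "IT",
                energy_kcal=float(rng.uniform(300, 4000)),
                complete=bool(rng.random() > 0.2),
            )
            for i in range(50)
        ]
        kept, excluded = index.apply_exclusions(records)
        assert len(kept) + len(excluded) == len(records)
        assert set(r.subject_id for r in kept).isdisjoint(
            r.subject_id for r, _ in excluded
        )


def test_example_spec_loads_and_scores_16_components():
    specs = index.example_component_specs()
    assert len(specs) == index.N_COMPONENTS
    # a subject hitting every full-score cutoff scores the maximum
    intakes = {}
    for s in specs:
        intakes[s.name] = s.full_score_cutoff
    records = [index.IntakeRecord("S1", "Italy", intakes)]
    table = index.score_intake_table(records, specs)
    assert table.loc[0, "index"] == pytest.approx(160.0)
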