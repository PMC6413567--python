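"""Synthetic two-visit, two-arm, multi-country adherence cohorts.

Generates cohorts with the statistical structure the correction model
assumes: country-specific baseline levels of a 0-160 diet-adherence
index, an intervention effect applied at the follow-up visit, additive
country-level yearly sinusoidal seasonality, between-subject spread of
the true baseline, and within-subject (measurement) noise at each visit.
Ground truth is returned alongside the observations so that parameter
recovery can be tested.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "CountrySpec",
    "CohortConfig",
    "SubjectTruth",
    "VisitRecord",
    "seasonal_value",
    "generate_cohort",
    "default_countries",
    "default_config",
    "records_to_frame",
    "frame_to_records",
    "write_cohort_csv",
    "read_cohort_csv",
    "truth_to_frame",
]

#: Day count used to map a day of the year to a year fraction.
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CountrySpec:
    """Generating parameters for one country.

    ``baseline_mean`` is the country's mean true adherence index (points
    on the 0-160 scale), ``effect_mean`` the mean intervention-arm shift
    at follow-up, and the two seasonal weights parameterize the yearly
    oscillation ``ws*sin(2*pi*t) + wc*cos(2*pi*t)`` added to every
    observation.
    """

    name: str
    n_subjects: int
    baseline_mean: float
    effect_mean: float
    seasonal_weight_sin: float = 0.0
    seasonal_weight_cos: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError(f"{self.name}: n_subjects must be > 0")
        if not 0.0 <= self.baseline_mean <= 160.0:
            raise ConfigurationError(
                f"{self.name}: baseline_mean {self.baseline_mean} outside [0, 160]"
            )
        if self.seasonal_amplitude > self.baseline_mean:
            raise ConfigurationError(
                f"{self.name}: seasonal amplitude exceeds baseline mean"
            )

    @property
    def seasonal_amplitude(self) -> float:
        """Half-range of the seasonal oscillation, in index points."""
        return math.hypot(self.seasonal_weight_sin, self.seasonal_weight_cos)


def _country_spec(name, n, baseline, effect, amplitude, peak_fraction) -> CountrySpec:
    phi = 2.0 * math.pi * peak_fraction
    return CountrySpec(
        name=name,
        n_subjects=n,
        baseline_mean=baseline,
        effect_mean=effect,
        seasonal_weight_sin=amplitude * math.sin(phi),
        seasonal_weight_cos=amplitude * math.cos(phi),
    )


def default_countries() -> list[CountrySpec]:
    """The five-country configuration emulating the study cohort.

    Sample sizes 241/251/235/222/184 (total 1,133); baselines near 80
    points with the Netherlands offset to 87; a 20-point intervention
    effect except France, where it is nearly double (38); seasonal
    peak-to-trough of 4 points in France and Poland, 2.5 in Italy and
    1 in the UK and the Netherlands, peaking near mid-year.
    """
    return [
        _country_spec("Italy", 241, 80.0, 20.0, 1.25, 0.50),
        _country_spec("United Kingdom", 251, 80.0, 20.0, 0.5, 0.35),
        _country_spec("Netherlands", 235, 87.0, 20.0, 0.5, 0.65),
        _country_spec("Poland", 222, 80.0, 20.0, 2.0, 0.55),
        _country_spec("France", 184, 80.0, 38.0, 2.0, 0.45),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Full generating configuration for a synthetic cohort.

    ``sigma_meas`` is the within-subject (measurement) SD per visit and
    ``sigma_between`` the between-subject SD of the true baseline; their
    ratio is the quantity the null model and the hierarchical model both
    estimate.  ``control_drift_fraction`` is the participation effect for
    controls expressed as a fraction of the country intervention effect.
    ``include_between_visit_change`` adds an extra N(0, change_sd) true
    change between visits to every subject (used by regression-to-the-mean
    experiments; off for the stable-controls cohort).
    """

    countries: list[CountrySpec] = field(default_factory=default_countries)
    sigma_between: float = 16.0 / 1.03
    sigma_meas: float = 16.0
    sigma_effect: float = 5.0
    control_drift_fraction: float = 0.05
    include_between_visit_change: bool = False
    change_sd: float = 0.0
    visit_gap_months_range: tuple[float, float] = (10.0, 14.0)
    date_sampling: str = "uniform-over-year"
    fixed_t0_fraction: float = 0.0
    clip_scores: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.countries:
            raise ConfigurationError("country list is empty")
        for sd_name in ("sigma_between", "sigma_meas", "sigma_effect", "change_sd"):
            if getattr(self, sd_name) < 0:
                raise ConfigurationError(f"{sd_name} must be >= 0")
        if not 0.0 <= self.control_drift_fraction <= 1.0:
            raise ConfigurationError("control_drift_fraction must be in [0, 1]")
        lo, hi = self.visit_gap_months_range
        if not 0 < lo <= hi:
            raise ConfigurationError("visit_gap_months_range must be 0 < lo <= hi")
        if self.date_sampling not in ("uniform-over-year", "fixed"):
            raise ConfigurationError(
                f"unknown date_sampling {self.date_sampling!r}"
            )

    @property
    def n_subjects(self) -> int:
        return sum(c.n_subjects for c in self.countries)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["visit_gap_months_range"] = list(self.visit_gap_months_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "countries" in d:
            d["countries"] = [
                c if isinstance(c, CountrySpec) else CountrySpec(**c)
                for c in d["countries"]
            ]
        if "visit_gap_months_range" in d:
            d["visit_gap_months_range"] = tuple(d["visit_gap_months_range"])
        return cls(**d)


@dataclass(frozen=True)
class SubjectTruth:
    """Latent generating values for one synthetic subject."""

    subject_id: str
    country: str
    arm: str
    true_baseline: float
    true_effect: float
    t0_fraction: float
    t1_fraction: float
    t1_elapsed_years: float


@dataclass(frozen=True)
class VisitRecord:
    """One observed adherence measurement (one subject-visit row)."""

    subject_id: str
    country: str
    arm: str
    visit: str  # "T0" | "T1"
    date_fraction: float
    observed_score: float


def seasonal_value(weight_sin: float, weight_cos: float, t) -> float | np.ndarray:
    """Additive seasonal term ``ws*sin(2*pi*t) + wc*cos(2*pi*t)``.

    ``t`` is a year fraction; values outside [0, 1) wrap by periodicity
    (the oscillation has an exact one-year period and zero yearly mean).
    """
    t = np.asarray(t, dtype=float)
    out = weight_sin * np.sin(2.0 * np.pi * t) + weight_cos * np.cos(2.0 * np.pi * t)
    return out if out.ndim else float(out)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[VisitRecord], list[SubjectTruth]]:
    """Draw a full synthetic cohort; deterministic given ``config.seed``.

    Each subject contributes exactly two records:

    * T0: ``true_baseline + season(country, t0) + e0``
    * T1: ``true_baseline + true_effect + season(country, t1) + e1``

    with ``e0, e1 ~ N(0, sigma_meas)`` independent.  Intervention-arm
    true effects are drawn ``N(effect_mean, sigma_effect)``; control-arm
    true effects are ``control_drift_fraction * effect_mean``.  When
    ``include_between_visit_change`` is on, an additional
    ``N(0, change_sd)`` true change is added to every subject's T1.
    Arms are balanced within each country.  Observed scores are not
    clipped to [0, 160] unless ``clip_scores`` is set (clipping biases
    variance estimates and is off by default).
    """
    rng = np.random.default_rng(config.seed)
    records: list[VisitRecord] = []
    truths: list[SubjectTruth] = []
    lo_m, hi_m = config.visit_gap_months_range

    for spec in config.countries:
        n = spec.n_subjects
        # balanced randomized arm assignment within country
        arms = np.array(["intervention"] * (n // 2) + ["control"] * (n - n // 2))
        rng.shuffle(arms)

        baselines = rng.normal(spec.baseline_mean, config.sigma_between, size=n)
        effects = np.where(
            arms == "intervention",
            rng.normal(spec.effect_mean, config.sigma_effect, size=n),
            config.control_drift_fraction * spec.effect_mean,
        )
        if config.include_between_visit_change and config.change_sd > 0:
            effects = effects + rng.normal(0.0, config.change_sd, size=n)

        if config.date_sampling == "uniform-over-year":
            t0 = rng.uniform(0.0, 1.0, size=n)
        else:
            t0 = np.full(n, config.fixed_t0_fraction % 1.0)
        gap_years = rng.uniform(lo_m, hi_m, size=n) / 12.0
        t1 = (t0 + gap_years) % 1.0

        noise = rng.normal(0.0, config.sigma_meas, size=(n, 2))
        s0 = seasonal_value(spec.seasonal_weight_sin, spec.seasonal_weight_cos, t0)
        s1 = seasonal_value(spec.seasonal_weight_sin, spec.seasonal_weight_cos, t1)
        y0 = baselines + s0 + noise[:, 0]
        y1 = baselines + effects + s1 + noise[:, 1]
        if config.clip_scores:
            y0 = np.clip(y0, 0.0, 160.0)
            y1 = np.clip(y1, 0.0, 160.0)

        prefix = "".join(w[0] for w in spec.name.split()).upper()
        for i in range(n):
            sid = f"{prefix}{i + 1:04d}"
            truths.append(
                SubjectTruth(
                    subject_id=sid,
                    country=spec.name,
                    arm=str(arms[i]),
                    true_baseline=float(baselines[i]),
                    true_effect=float(effects[i]),
                    t0_fraction=float(t0[i]),
                    t1_fraction=float(t1[i]),
                    t1_elapsed_years=float(gap_years[i]),
                )
            )
            records.append(
                VisitRecord(sid, spec.name, str(arms[i]), "T0", float(t0[i]), float(y0[i]))
            )
            records.append(
                VisitRecord(sid, spec.name, str(arms[i]), "T1", float(t1[i]), float(y1[i]))
            )
    return records, truths


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default study-like cohort configuration (1,133 subjects)."""
    return CohortConfig(seed=seed, **overrides)


# ---------------------------------------------------------------- I/O

_COHORT_COLUMNS = ["subject_id", "country", "arm", "visit", "date_fraction", "observed_score"]


def records_to_frame(records: list[VisitRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=_COHORT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[VisitRecord]:
    missing = set(_COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigurationError(f"cohort table missing columns: {sorted(missing)}")
    return [
        VisitRecord(
            str(row.subject_id),
            str(row.country),
            str(row.arm),
            str(row.visit),
            float(row.date_fraction),
            float(row.observed_score),
        )
        for row in frame.itertuples(index=False)
    ]


def write_cohort_csv(records: list[VisitRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[VisitRecord]:
    # round_trip parsing so written cohorts reload to identical floats
    return frame_to_records(pd.read_csv(path, float_precision="round_trip"))


def truth_to_frame(truths: list[SubjectTruth]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in truths])
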