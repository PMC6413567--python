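"""Config-driven continuous diet-adherence scorer (0-160 points).

The index sums 16 continuous component scores, each in [0, 10].
Components come in three kinds:

* ``adequacy`` — more is better; score ramps linearly from 0 points at
  ``zero_score_cutoff`` up to 10 points at ``full_score_cutoff``.
* ``limit`` — less is better; 10 points at or below ``full_score_cutoff``
  and 0 points at or above ``zero_score_cutoff`` (the ordering reverses).
* ``range`` — 10 points inside a [full_min, full_max] band with linear
  ramps down to 0 at the outer zero cutoffs (e.g. whole grains, eggs).

Some cutoffs are defined relative to the per-country intake
distribution (e.g. an 85th-percentile cap); ``derive_caps`` resolves
those from observed intakes.  Exclusion rules (incomplete diaries,
missing supplement data, implausible energy intake) mirror common food
record cleaning practice.

The exact cutoff constants for any particular guideline set are study
specific; the shipped example spec is illustrative only, and every
cutoff is configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, InputError

__all__ = [
    "ComponentSpec",
    "CapRule",
    "IntakeRecord",
    "score_component",
    "compute_index",
    "derive_caps",
    "apply_exclusions",
    "load_component_specs",
    "example_component_specs",
    "score_intake_table",
    "N_COMPONENTS",
    "MAX_INDEX",
]

N_COMPONENTS = 16
MAX_INDEX = 160.0


@dataclass(frozen=True)
class CapRule:
    """Percentile-based cutoff derived from per-country intakes."""

    percentile: float
    per_country: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile <= 100.0:
            raise ConfigurationError("cap percentile must be in [0, 100]")


@dataclass(frozen=True)
class ComponentSpec:
    """Scoring rule for one diet component.

    For ``range`` components, ``full_score_cutoff``/``zero_score_cutoff``
    describe the lower ramp and ``full_score_cutoff_high``/
    ``zero_score_cutoff_high`` the upper one.
    """

    name: str
    kind: str  # adequacy | limit | range
    full_score_cutoff: float
    zero_score_cutoff: float
    full_score_cutoff_high: float | None = None
    zero_score_cutoff_high: float | None = None
    cap_rule: CapRule | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("adequacy", "limit", "range"):
            raise ConfigurationError(f"{self.name}: unknown kind {self.kind!r}")
        for v in (self.full_score_cutoff, self.zero_score_cutoff):
            if v < 0:
                raise ConfigurationError(f"{self.name}: cutoffs must be non-negative")
        if self.kind == "adequacy" and not self.zero_score_cutoff < self.full_score_cutoff:
            raise ConfigurationError(
                f"{self.name}: adequacy needs zero_score_cutoff < full_score_cutoff"
            )
        if self.kind == "limit" and not self.full_score_cutoff < self.zero_score_cutoff:
            raise ConfigurationError(
                f"{self.name}: limit needs full_score_cutoff < zero_score_cutoff"
            )
        if self.kind == "range":
            if self.full_score_cutoff_high is None or self.zero_score_cutoff_high is None:
                raise ConfigurationError(f"{self.name}: range needs upper cutoffs")
            ok = (
                self.zero_score_cutoff
                <= self.full_score_cutoff
                <= self.full_score_cutoff_high
                <= self.zero_score_cutoff_high
            )
            if not ok:
                raise ConfigurationError(f"{self.name}: range cutoffs out of order")


@dataclass(frozen=True)
class IntakeRecord:
    """Per-subject component intakes plus completeness metadata."""

    subject_id: str
    country: str
    intakes: dict = field(default_factory=dict)
    energy_kcal: float = 2000.0
    complete: bool = True
    supplement_data_present: bool = True

    def __post_init__(self) -> None:
        for name, amount in self.intakes.items():
            if amount < 0:
                raise InputError(f"{self.subject_id}: negative intake for {name}")


def score_component(intake: float, spec: ComponentSpec) -> float:
    """Score one component intake on the continuous [0, 10] scale.

    Piecewise-linear interpolation between the 0-point and 10-point
    cutoffs, clamped to [0, 10]; adequacy components are non-decreasing
    in intake, limit components non-increasing, range components score
    10 inside the band and ramp to 0 outside it.
    """
    if intake < 0:
        raise InputError(f"{spec.name}: negative intake {intake}")
    if spec.kind == "adequacy":
        xp = [spec.zero_score_cutoff, spec.full_score_cutoff]
        fp = [0.0, 10.0]
    elif spec.kind == "limit":
        xp = [spec.full_score_cutoff, spec.zero_score_cutoff]
        fp = [10.0, 0.0]
    else:  # range
        xp = [
            spec.zero_score_cutoff,
            spec.full_score_cutoff,
            spec.full_score_cutoff_high,
            spec.zero_score_cutoff_high,
        ]
        fp = [0.0, 10.0, 10.0, 0.0]
        # collapse ties to keep np.interp well defined
        xp, fp = zip(*dict(zip(xp, fp)).items())
    return float(np.clip(np.interp(intake, xp, fp), 0.0, 10.0))


def compute_index(component_scores) -> float:
    """Sum 16 component scores into the 0-160 adherence index."""
    scores = np.asarray(list(component_scores), dtype=float)
    if scores.shape != (N_COMPONENTS,):
        raise InputError(f"expected {N_COMPONENTS} component scores, got {scores.shape}")
    if np.any(scores < 0) or np.any(scores > 10):
        raise InputError("component scores must be in [0, 10]")
    return float(scores.sum())


def _empirical_quantile(values: np.ndarray, percentile: float) -> float:
    # linear-interpolation empirical quantile
    return float(np.quantile(values, percentile / 100.0, method="linear"))


def derive_caps(
    intakes: list[IntakeRecord], specs: list[ComponentSpec]
) -> list[ComponentSpec]:
    """Resolve percentile-based cutoffs from observed per-country intakes.

    For each component with a ``cap_rule``, the cutoff that caps the
    score (the zero-score cutoff for ``limit`` components, the
    full-score cutoff for ``adequacy``, the upper band edge for
    ``range``) is replaced by the stated percentile of the observed
    intakes.  With ``per_country`` caps the returned list contains one
    spec per (component, country); country-independent specs pass
    through unchanged.
    """
    out: list[ComponentSpec] = []
    countries = sorted({r.country for r in intakes})
    for spec in specs:
        if spec.cap_rule is None:
            out.append(spec)
            continue
        strata = countries if spec.cap_rule.per_country else [None]
        for country in strata:
            rows = [r for r in intakes if country is None or r.country == country]
            vals = np.array(
                [r.intakes[spec.name] for r in rows if spec.name in r.intakes]
            )
            if vals.size == 0:
                raise InputError(
                    f"no intake data for component {spec.name!r} in stratum "
                    f"{country or 'all'}"
                )
            cut = _empirical_quantile(vals, spec.cap_rule.percentile)
            updates: dict = {"cap_rule": None}
            if country is not None:
                updates["name"] = f"{spec.name}@{country}"
            if spec.kind == "limit":
                updates["zero_score_cutoff"] = max(cut, spec.full_score_cutoff + 1e-12)
            elif spec.kind == "adequacy":
                updates["full_score_cutoff"] = max(cut, spec.zero_score_cutoff + 1e-12)
            else:
                updates["zero_score_cutoff_high"] = max(cut, spec.full_score_cutoff_high)
            out.append(dataclasses.replace(spec, **updates))
    return out


#: Exclusion rules in fixed priority order: (tag, predicate).
EXCLUSION_RULES = (
    ("incomplete-diary", lambda r: not r.complete),
    ("missing-supplement-data", lambda r: not r.supplement_data_present),
    ("low-energy", lambda r: r.energy_kcal < 500.0),
    ("high-energy", lambda r: r.energy_kcal > 3500.0),
)


def apply_exclusions(
    records: list[IntakeRecord],
) -> tuple[list[IntakeRecord], list[tuple[IntakeRecord, str]]]:
    """Partition intake records into kept and excluded-with-reason.

    Excludes incomplete diaries, records with missing supplement data,
    and implausible energy intakes (< 500 or > 3500 kcal/day; the
    boundary values themselves are kept).  Each excluded record is
    tagged with the first matching rule.
    """
    kept: list[IntakeRecord] = []
    excluded: list[tuple[IntakeRecord, str]] = []
    for rec in records:
        for tag, pred in EXCLUSION_RULES:
            if pred(rec):
                excluded.append((rec, tag))
                break
        else:
            kept.append(rec)
    return kept, excluded


# ---------------------------------------------------------------- spec I/O


def _spec_from_dict(d: dict) -> ComponentSpec:
    d = dict(d)
    cap = d.get("cap_rule")
    if cap is not None and not isinstance(cap, CapRule):
        d["cap_rule"] = CapRule(**cap)
    return ComponentSpec(**d)


def load_component_specs(path) -> list[ComponentSpec]:
    """Load component specs from a YAML file (a list under ``components``)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    items = doc["components"] if isinstance(doc, dict) else doc
    return [_spec_from_dict(d) for d in items]


def example_component_specs() -> list[ComponentSpec]:
    """The illustrative 16-component example spec shipped with the package."""
    ref = resources.files("nuage").joinpath("data/example_components.yaml")
    with resources.as_file(ref) as path:
        return load_component_specs(path)


def score_intake_table(
    records: list[IntakeRecord], specs: list[ComponentSpec]
) -> pd.DataFrame:
    """Score a table of intakes: one row per kept subject plus the index.

    Applies exclusions, resolves percentile caps from the kept records,
    scores each component and sums the index.  Per-country resolved
    specs (``name@Country``) are matched back to each subject's country.
    """
    kept, excluded = apply_exclusions(records)
    if not kept:
        return pd.DataFrame(columns=["subject_id", "country", "index"])
    resolved = derive_caps(kept, specs)
    by_key = {s.name: s for s in resolved}
    base_names = [s.name for s in specs]
    rows = []
    for rec in kept:
        scores = {}
        for name in base_names:
            spec = by_key.get(f"{name}@{rec.country}", by_key.get(name))
            if spec is None:
                raise InputError(f"no resolved spec for component {name!r}")
            scores[name] = score_component(rec.intakes.get(name, 0.0), spec)
        row = {"subject_id": rec.subject_id, "country": rec.country, **scores}
        row["index"] = compute_index([scores[n] for n in base_names])
        rows.append(row)
    return pd.DataFrame(rows)
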