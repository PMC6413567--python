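"""Regression-to-the-mean null model for paired adherence measurements.

When a noisy score is measured at baseline (T0) and follow-up (T1), the
measurement noise alone induces a negative correlation between the T0
value and the observed change (T1 - T0).  This module simulates that
idealized measurement process, gives the closed-form expectation of the
correlation as a function of the within/between variability ratio
``lambda = sigma_meas / sigma_between``, and inverts an observed
correlation back into an estimate of that ratio.

The idealized model: true baselines B ~ N(0, 1); an optional true change
C ~ N(0, 1) between visits; independent measurement errors
e0, e1 ~ N(0, lambda) at each visit.  Observed T0 = B + e0 and
T1 = B + C + e1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import VisitRecord
from .exceptions import ConfigurationError, InputError

__all__ = [
    "NullModelConfig",
    "CorrelationCurve",
    "LambdaEstimate",
    "expected_correlation",
    "simulate_null",
    "invert_curve",
    "regression_to_mean_table",
]

#: Supremum of |correlation| attainable under the null model (lambda -> inf).
MAX_ABS_CORRELATION = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class NullModelConfig:
    """Simulation settings for the null-model correlation curve."""

    n_subjects: int = 1133
    lambda_grid: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 3.0, 15), 6))
    reps: int = 50
    include_change: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if any(l < 0 for l in self.lambda_grid):
            raise ConfigurationError("lambda grid values must be >= 0")
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")


@dataclass(frozen=True)
class CorrelationCurve:
    """Monte-Carlo map from lambda to the difference-baseline correlation.

    ``correlations`` holds the per-rep Pearson correlations with shape
    ``(len(lambdas), reps)``; ``mean`` and ``mc_se`` are the per-lambda
    Monte-Carlo mean and standard error of that mean.
    """

    lambdas: np.ndarray
    correlations: np.ndarray
    include_change: bool

    @property
    def mean(self) -> np.ndarray:
        return self.correlations.mean(axis=1)

    @property
    def mc_se(self) -> np.ndarray:
        reps = self.correlations.shape[1]
        if reps == 1:
            return np.zeros(len(self.lambdas))
        return self.correlations.std(axis=1, ddof=1) / np.sqrt(reps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "mean_correlation": self.mean,
                "mc_se": self.mc_se,
                "reps": self.correlations.shape[1],
            }
        )


@dataclass(frozen=True)
class LambdaEstimate:
    """Inversion result: point estimate of lambda with per-rep IQR."""

    estimate: float
    iqr: tuple[float, float]
    observed_r: float
    ratio_greater_than_one: bool
    per_rep: np.ndarray = field(repr=False, default=None)


def expected_correlation(lam, include_change: bool = True):
    """Closed-form Pearson correlation between T0 and (T1 - T0).

    With the between-visit change term the correlation is
    ``-lam^2 / sqrt((1 + lam^2) (1 + 2 lam^2))``; without it,
    ``-lam / sqrt(2 (1 + lam^2))``.  Both are 0 at ``lam = 0`` and tend
    to ``-1/sqrt(2)`` as ``lam -> inf``.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0):
        raise InputError("lambda must be >= 0")
    l2 = lam_arr**2
    if include_change:
        out = -l2 / np.sqrt((1.0 + l2) * (1.0 + 2.0 * l2))
    else:
        out = -lam_arr / np.sqrt(2.0 * (1.0 + l2))
    return out if out.ndim else float(out)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return np.nan
    return float((xc @ yc) / denom)


def simulate_null(config: NullModelConfig) -> CorrelationCurve:
    """Monte-Carlo estimate of the difference-baseline correlation curve.

    For each lambda and each rep, draws ``n_subjects`` idealized paired
    measurements and records the Pearson correlation between T0 and
    (T1 - T0).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lambdas = np.asarray(config.lambda_grid, dtype=float)
    corrs = np.empty((len(lambdas), config.reps))
    n = config.n_subjects
    for i, lam in enumerate(lambdas):
        for r in range(config.reps):
            b = rng.standard_normal(n)
            c = rng.standard_normal(n) if config.include_change else 0.0
            e0 = lam * rng.standard_normal(n)
            e1 = lam * rng.standard_normal(n)
            t0 = b + e0
            t1 = b + c + e1
            corrs[i, r] = _pearson(t0, t1 - t0)
    return CorrelationCurve(lambdas, corrs, config.include_change)


def _invert_one(lambdas: np.ndarray, curve_r: np.ndarray, observed_r: float) -> float:
    # Enforce monotone non-increasing r over lambda (MC noise can break it),
    # then invert by piecewise-linear interpolation; ties resolve to the
    # smaller lambda because the first crossing is taken.  Degenerate grid
    # points (NaN correlation, e.g. lambda=0 without a change term) are
    # dropped before interpolating.
    finite = np.isfinite(curve_r)
    if not finite.any():
        raise InputError("correlation curve has no finite values")
    lambdas, curve_r = lambdas[finite], curve_r[finite]
    r_mono = np.minimum.accumulate(curve_r)
    # np.interp needs increasing x: interpolate lambda as a function of -r
    return float(np.interp(-observed_r, -r_mono, lambdas))


def invert_curve(curve: CorrelationCurve, observed_r: float) -> LambdaEstimate:
    """Invert an observed difference-baseline correlation into lambda.

    The point estimate inverts the Monte-Carlo mean curve by monotone
    piecewise-linear interpolation; the IQR inverts each per-rep curve
    realization and takes the [25%, 75%] quantiles of the resulting
    lambda estimates.  ``ratio_greater_than_one`` flags estimates whose
    IQR lies entirely above 1.
    """
    if observed_r > 0:
        raise InputError("observed correlation must be <= 0 under the null model")
    if observed_r <= -MAX_ABS_CORRELATION:
        raise InputError(
            f"observed correlation {observed_r} is at or beyond the attainable "
            f"limit -1/sqrt(2) ~ {-MAX_ABS_CORRELATION:.4f}; no lambda attains it"
        )
    order = np.argsort(curve.lambdas)
    lambdas = curve.lambdas[order]
    est = _invert_one(lambdas, curve.mean[order], observed_r)
    per_rep = np.array(
        [
            _invert_one(lambdas, curve.correlations[order, r], observed_r)
            for r in range(curve.correlations.shape[1])
        ]
    )
    q25, q75 = np.percentile(per_rep, [25.0, 75.0])
    return LambdaEstimate(
        estimate=est,
        iqr=(float(q25), float(q75)),
        observed_r=float(observed_r),
        ratio_greater_than_one=bool(q25 > 1.0),
        per_rep=per_rep,
    )


def regression_to_mean_table(records: list[VisitRecord]) -> pd.DataFrame:
    """Per-arm summary of the observed change and its baseline correlation.

    Returns one row per arm with the mean difference (T1 - T0), the
    sample SD of the difference, and the Pearson correlation between the
    difference and the T0 score (NaN when the correlation is undefined,
    e.g. zero variance).  Every subject must have both visits.
    """
    frame = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "arm": [r.arm for r in records],
            "visit": [r.visit for r in records],
            "score": [r.observed_score for r in records],
        }
    )
    counts = frame.pivot_table(
        index="subject_id", columns="visit", values="score", aggfunc="count"
    ).reindex(columns=["T0", "T1"])
    bad = counts.index[(counts.fillna(0) != 1).any(axis=1)].tolist()
    if bad:
        raise InputError(f"subjects without exactly one T0 and one T1 visit: {bad}")

    wide = frame.pivot(index="subject_id", columns="visit", values="score")
    arms = frame.drop_duplicates("subject_id").set_index("subject_id")["arm"]
    rows = []
    for arm, idx in arms.groupby(arms).groups.items():
        t0 = wide.loc[idx, "T0"].to_numpy()
        diff = wide.loc[idx, "T1"].to_numpy() - t0
        rows.append(
            {
                "arm": arm,
                "n": len(idx),
                "mean_difference": float(diff.mean()),
                "difference_sd": float(diff.std(ddof=1)) if len(idx) > 1 else 0.0,
                "diff_t0_r": _pearson(t0, diff) if len(idx) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
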