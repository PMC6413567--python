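"""End-to-end orchestration: cohort -> null model -> Bayesian correction.

Chains the package stages and writes the analysis outputs as CSV/JSON
with a run report (seeds, per-stage runtimes, diagnostics, output
manifest with checksums).  All outputs are deterministic given the
seeds in the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import model as model_mod
from . import rtm as rtm_mod
from .exceptions import NuageError

__all__ = ["PipelineConfig", "RunReport", "StageError", "run_pipeline", "load_config"]


class StageError(NuageError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage: {stage}: {cause}")


@dataclass(frozen=True)
class PipelineConfig:
    """One config object with a section per stage."""

    cohort: cohort_mod.CohortConfig = field(default_factory=cohort_mod.CohortConfig)
    rtm: rtm_mod.NullModelConfig = field(default_factory=rtm_mod.NullModelConfig)
    model: model_mod.ModelSpec = field(default_factory=model_mod.ModelSpec)
    cohort_csv: str | None = None  # fit a user-supplied cohort instead of simulating

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = {}
        if "cohort" in d:
            kw["cohort"] = cohort_mod.CohortConfig.from_dict(d["cohort"])
        if "rtm" in d:
            kw["rtm"] = rtm_mod.NullModelConfig(
                **{**d["rtm"], "lambda_grid": tuple(d["rtm"].get("lambda_grid", rtm_mod.NullModelConfig().lambda_grid))}
            )
        if "model" in d:
            kw["model"] = model_mod.ModelSpec(**d["model"])
        if "cohort_csv" in d:
            kw["cohort_csv"] = d["cohort_csv"]
        return cls(**kw)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    """What a pipeline run did: config echo, seeds, runtimes, outputs."""

    config: dict
    seeds: dict
    runtimes: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(out_dir, config: PipelineConfig | None = None) -> RunReport:
    """Run every stage and write the six analysis outputs to ``out_dir``.

    Outputs: ``cohort.csv`` (the analyzed records), ``arm_summary.csv``
    (per-arm change table), ``inversion.csv`` (null-model variance-ratio
    inversion), ``posterior_summary.csv``, ``corrected_scores.csv`` and
    ``seasonality.csv``.  The generating truth table (synthetic runs
    only) and ``report.json`` are written alongside.  Any stage failure
    raises :class:`StageError` naming the stage.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config={
            "cohort": config.cohort.to_dict(),
            "rtm": dataclasses.asdict(config.rtm),
            "model": dataclasses.asdict(config.model),
            "cohort_csv": config.cohort_csv,
        },
        seeds={
            "cohort": config.cohort.seed,
            "rtm": config.rtm.seed,
            "model": config.model.seed,
        },
    )
    manifest_paths: list[Path] = []

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                report.runtimes[name] = round(time.perf_counter() - self.t, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc

        return _Ctx()

    with stage("simulate"):
        if config.cohort_csv is not None:
            if not Path(config.cohort_csv).exists():
                raise FileNotFoundError(config.cohort_csv)
            records = cohort_mod.read_cohort_csv(config.cohort_csv)
            truths = None
        else:
            records, truths = cohort_mod.generate_cohort(config.cohort)
        cohort_path = out / "cohort.csv"
        cohort_mod.write_cohort_csv(records, cohort_path)
        manifest_paths.append(cohort_path)
        if truths is not None:
            cohort_mod.truth_to_frame(truths).to_csv(out / "truth.csv", index=False)

    with stage("rtm"):
        table = rtm_mod.regression_to_mean_table(records)
        table.to_csv(out / "arm_summary.csv", index=False)
        manifest_paths.append(out / "arm_summary.csv")
        curve = rtm_mod.simulate_null(config.rtm)
        rows = []
        for _, row in table.iterrows():
            r = row["diff_t0_r"]
            if not np.isfinite(r) or r > 0 or r <= -rtm_mod.MAX_ABS_CORRELATION:
                continue
            est = rtm_mod.invert_curve(curve, float(r))
            rows.append(
                {
                    "arm": row["arm"],
                    "observed_r": est.observed_r,
                    "lambda_estimate": est.estimate,
                    "lambda_iqr_low": est.iqr[0],
                    "lambda_iqr_high": est.iqr[1],
                    "ratio_greater_than_one": est.ratio_greater_than_one,
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "arm",
                "observed_r",
                "lambda_estimate",
                "lambda_iqr_low",
                "lambda_iqr_high",
                "ratio_greater_than_one",
            ],
        ).to_csv(out / "inversion.csv", index=False)
        manifest_paths.append(out / "inversion.csv")

    with stage("build_inputs"):
        inputs = model_mod.build_inputs(records)

    with stage("fit"):
        fit = model_mod.fit_model(inputs, config.model)
        report.diagnostics = {
            "flags": fit.flags,
            "acceptance_fraction": fit.acceptance_fraction,
            "max_rhat": float(fit.diagnostics["rhat"].max()),
            "min_ess": float(fit.diagnostics["ess"].min()),
        }

    with stage("report"):
        summaries, var, seasonality = model_mod.summarize_posterior(fit)
        pd.DataFrame(
            [
                {
                    "parameter": s.parameter,
                    "mean": s.mean,
                    "hdi50_low": s.hdi50[0],
                    "hdi50_high": s.hdi50[1],
                    "hdi95_low": s.hdi95[0],
                    "hdi95_high": s.hdi95[1],
                    "per_repeat_means": ";".join(f"{m:.4f}" for m in s.per_repeat_means),
                    "rhat": s.rhat,
                    "ess": s.ess,
                }
                for s in summaries
            ]
        ).to_csv(out / "posterior_summary.csv", index=False)
        manifest_paths.append(out / "posterior_summary.csv")

        model_mod.correct_scores(fit).to_csv(out / "corrected_scores.csv", index=False)
        manifest_paths.append(out / "corrected_scores.csv")

        pd.DataFrame([dataclasses.asdict(s) for s in seasonality]).to_csv(
            out / "seasonality.csv", index=False
        )
        manifest_paths.append(out / "seasonality.csv")

    report.manifest = {p.name: _sha256(p) for p in manifest_paths}
    (out / "report.json").write_text(report.to_json())
    return report
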