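"""End-to-end pipeline: impute → estimate → assess → bootstrap → cohort stats.

Produces the analysis's table analogues as CSV files plus a structured
JSON summary carrying the package version, a config hash, the RNG seed
and the per-path decisions, so a run is fully reproducible and
mechanically comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path

import pandas as pd

from .assessment import apply_thresholds, assess
from .bootstrap import bootstrap_paths
from .cohort import cluster_by_grade, impute_column, symptom_frequencies
from .model_spec import ModelSpec, load_model, subhealth_model
from .pls import PLSPathModel
from .simulate import default_population, sample_cohort

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (all paths optional ⇒ synthetic)."""

    out_dir: str = "subhealth_run"
    indicators_csv: str | None = None
    symptoms_csv: str | None = None
    grades_csv: str | None = None
    model_path: str | None = None
    n: int = 627
    seed: int = 0
    scheme: str = "path"
    tol: float = 1e-7
    max_iter: int = 300
    n_boot: int = 5000
    alpha: float = 0.05
    top_symptoms: int = 50
    extra: dict = field(default_factory=dict)

    def model(self) -> ModelSpec:
        return load_model(self.model_path) if self.model_path else subhealth_model()

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # re-raise with the failing stage attached
        raise PipelineError(stage, str(exc)) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-phase analysis and write the report bundle.

    Returns a summary dict (also written as ``summary.json``).  Inputs are
    read from the configured CSVs; any missing input is generated from the
    packaged synthetic population at ``config.n`` / ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = _stage("model", config.model)
    pop = default_population(spec) if spec.construct_names == subhealth_model().construct_names else None

    if config.indicators_csv:
        indicators = _stage("load", pd.read_csv, config.indicators_csv)
        symptoms = pd.read_csv(config.symptoms_csv) if config.symptoms_csv else None
        grades = pd.read_csv(config.grades_csv, index_col=0) if config.grades_csv else None
        cluster_map = default_population().symptom_clusters
    else:
        cohort = _stage("generate", sample_cohort, pop or default_population(), config.n, config.seed)
        indicators, symptoms, grades = cohort.indicators, cohort.symptoms, cohort.sv_grades
        cluster_map = (pop or default_population()).symptom_clusters

    missing = [c for c in spec.indicator_names if c not in indicators.columns]
    if missing:
        raise PipelineError("impute", f"missing indicator column(s): {missing}")
    imputed = indicators.copy()
    for col in spec.indicator_names:
        try:
            imputed[col] = impute_column(indicators[col])
        except Exception as exc:
            raise PipelineError("impute", f"column {col!r}: {exc}") from exc

    pls = _stage(
        "estimate",
        lambda: PLSPathModel(
            model=spec, scheme=config.scheme, tol=config.tol, max_iter=config.max_iter
        ).fit(imputed),
    )
    report = _stage("assess", assess, pls, imputed)
    flags = apply_thresholds(report)
    boot = _stage(
        "bootstrap",
        bootstrap_paths,
        imputed,
        spec,
        n_boot=config.n_boot,
        seed=config.seed,
        alpha=config.alpha,
        scheme=config.scheme,
        tol=config.tol,
        max_iter=config.max_iter,
    )

    report.to_csv(str(out / "assessment"))
    boot.to_frame().to_csv(out / "paths_bootstrap.csv")
    flags["constructs"].to_csv(out / "threshold_flags_constructs.csv", na_rep="–")
    flags["indicators"].to_csv(out / "threshold_flags_indicators.csv", na_rep="–")
    flags["pairs"].to_csv(out / "threshold_flags_pairs.csv", na_rep="–")

    n_subjects = len(indicators)
    if symptoms is not None and len(symptoms):
        ranking = _stage("cohort", symptom_frequencies, symptoms, n_subjects, config.top_symptoms)
        ranking.to_csv(out / "symptom_ranking.csv", index=False)
        if grades is not None:
            matrix = _stage("cohort", cluster_by_grade, symptoms, cluster_map, grades)
            matrix.to_csv(out / "cluster_by_grade.csv")
    if grades is not None:
        dist = pd.concat(
            {dim: grades[dim].value_counts().sort_index() for dim in grades.columns}
        )
        dist.rename("count").to_csv(out / "grade_distribution.csv")

    summary = {
        "package_version": pkg_version("subhealth"),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_subjects": n_subjects,
        "converged": bool(pls.converged_),
        "iterations": int(pls.iterations_),
        "r_squared": {k: round(float(v), 6) for k, v in pls.r_squared_.items()},
        "paths": {
            name: {
                "coefficient": round(float(boot.original[name]), 6),
                "t": round(float(boot.t[name]), 4),
                "p": round(float(boot.p[name]), 6),
                "decision": str(boot.decision[name]),
            }
            for name in boot.original.index
        },
        "bootstrap": {
            "n_boot": boot.n_boot,
            "alpha": boot.alpha,
            "n_discarded": boot.n_discarded,
        },
        "symptom_positivity_rule": "severity >= 1",
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
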