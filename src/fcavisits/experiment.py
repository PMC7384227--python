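"""End-to-end experiment: simulate → disaggregate → predict → evaluate.

Reproduces the full evaluation design on a synthetic region: every
prediction method × attractiveness source × diagnosis combination is run
through the pipeline (need disaggregated from the district table, never
from the generating truth), scored against the simulated actual visits,
and collected into comparison matrices (methods × diagnoses) for the
rank correlation, explained variance, error-band and best-case-
attractiveness views.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .disaggregation import disaggregate_need
from .evaluation import EvaluationReport, evaluate, kruskal_wallis
from .fca import METHODS, run_method
from .io import PipelineConfig, config_from_dict, write_scenario
from .synthetic import ScenarioSpec, SyntheticScenario, generate_scenario
from .types import visits_column

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "write_bundle",
    "load_experiment_config",
]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    methods: tuple = METHODS
    attractiveness_sources: tuple = ("beds", "actual_visits")
    seed: int | None = None  # overrides scenario.seed when set


@dataclass
class ExperimentResult:
    synthetic: SyntheticScenario
    reports: list  # EvaluationReport per (method, diagnosis, source)
    predictions: pd.DataFrame  # long form across all runs
    kruskal: dict  # (diagnosis, source) -> {"H": ..., "p": ...}
    tables: dict  # name -> DataFrame (methods × diagnoses)

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.reports])


def _pivot(reports: list[EvaluationReport], value: str, source: str) -> pd.DataFrame:
    rows = [r.to_dict() for r in reports if r.attractiveness_source == source]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    return df.pivot(index="method", columns="diagnosis", values=value)


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentResult:
    """Run the full experimental design once, deterministically per seed."""
    config = config or ExperimentConfig()
    synthetic = generate_scenario(config.scenario, seed=config.seed)
    scenario = disaggregate_need(synthetic.scenario)
    diagnoses = [d.name for d in config.scenario.diagnoses]

    reports: list[EvaluationReport] = []
    pred_frames = []
    method_preds: dict = {}
    for diagnosis in diagnoses:
        actual_all = scenario.hospitals.set_index("hospital_id")[visits_column(diagnosis)]
        for source in config.attractiveness_sources:
            for method in config.methods:
                pred = run_method(scenario, diagnosis, method, source, config.pipeline)
                actual = actual_all.reindex(pred.visits.index).astype(float)
                reports.append(
                    evaluate(
                        pred.visits.to_numpy(),
                        actual.to_numpy(),
                        method=method,
                        diagnosis=diagnosis,
                        attractiveness_source=source,
                        bands=config.pipeline.bands,
                    )
                )
                pred_frames.append(pred.to_frame(actual))
                method_preds[(diagnosis, source, method)] = pred.visits

    kruskal = {}
    for diagnosis in diagnoses:
        for source in config.attractiveness_sources:
            groups = {
                m: method_preds[(diagnosis, source, m)].to_numpy()
                for m in config.methods
                if m != "closest" and (diagnosis, source, m) in method_preds
            }
            if len(groups) >= 2:
                H, p = kruskal_wallis(groups)
                kruskal[f"{diagnosis}/{source}"] = {"H": H, "p": p}

    tables = {
        "spearman_beds": _pivot(reports, "spearman_rho", "beds"),
        "r_squared_beds": _pivot(reports, "r_squared", "beds"),
        "spearman_actual_visits": _pivot(reports, "spearman_rho", "actual_visits"),
    }
    for band in config.pipeline.bands:
        key = f"band_{int(round(band * 100))}pct"
        tables[f"{key}_beds"] = _pivot(reports, key, "beds")

    return ExperimentResult(
        synthetic=synthetic,
        reports=reports,
        predictions=pd.concat(pred_frames, ignore_index=True),
        kruskal=kruskal,
        tables=tables,
    )


def write_bundle(result: ExperimentResult, outdir: str | Path) -> None:
    """Persist every artifact of an experiment run.

    Writes the scenario files, all predictions, the per-run reports
    (JSON), the Kruskal–Wallis comparisons, and each comparison matrix
    both as CSV and as an aligned plain-text table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_scenario(result.synthetic.scenario, outdir / "scenario")
    result.predictions.to_csv(outdir / "predictions.csv", index=False)
    result.report_frame().to_csv(outdir / "reports.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {
                "reports": [r.to_dict() for r in result.reports],
                "kruskal_wallis": result.kruskal,
            },
            fh,
            indent=2,
        )
    for name, table in result.tables.items():
        table.to_csv(outdir / f"table_{name}.csv")
        with open(outdir / f"table_{name}.txt", "w") as fh:
            fh.write(table.round(3).to_string())
            fh.write("\n")


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    """Load an experiment YAML (scenario + pipeline + run lists)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scen_kwargs = dict(raw.get("scenario") or {})
    if "diagnoses" in scen_kwargs:
        from .synthetic import DiagnosisSpec

        scen_kwargs["diagnoses"] = tuple(
            DiagnosisSpec(**d) for d in scen_kwargs["diagnoses"]
        )
    if "choice_decay" in scen_kwargs:
        from .io import _decay_from_dict

        scen_kwargs["choice_decay"] = _decay_from_dict(scen_kwargs["choice_decay"])
    config = ExperimentConfig(scenario=ScenarioSpec(**scen_kwargs))
    config.pipeline = config_from_dict(raw)  # pipeline keys live at top level
    if "methods" in raw:
        config.methods = tuple(raw["methods"])
    if "attractiveness" in raw:
        config.attractiveness_sources = tuple(raw["attractiveness"])
    if "seed" in raw:
        config.seed = int(raw["seed"])
    return config
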