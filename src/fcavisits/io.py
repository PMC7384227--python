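"""Readers/writers for scenario tables and the experiment configuration.

On-disk formats are plain delimited text with a header:

* ``cells.csv`` — cell_id, x_km, y_km, population, municipality_id, district_id
* ``hospitals.csv`` — hospital_id, x_km, y_km, beds_<specialty>..., visits_<diagnosis>...
* ``district_need.csv`` — district_id, age_group, sex, diagnosis, count
* ``travel_times.csv`` — long form: cell_id, hospital_id, minutes
* ``municipality_strata.csv`` — municipality_id, age_group, sex, population
* config — YAML naming decay families/parameters, catchment, thresholds, seed
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decay import DecaySpec
from .types import Scenario, TravelTimeMatrix, beds_column, visits_column

__all__ = [
    "SchemaError",
    "ValidationError",
    "read_scenario",
    "write_scenario",
    "exclude_hospitals",
    "PipelineConfig",
    "load_config",
    "config_from_dict",
]


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """A type invariant is violated (negative count, broken hierarchy, ...)."""


_CELL_COLUMNS = ["cell_id", "x_km", "y_km", "population", "municipality_id", "district_id"]
_HOSPITAL_COLUMNS = ["hospital_id", "x_km", "y_km"]
_NEED_COLUMNS = ["district_id", "age_group", "sex", "diagnosis", "count"]
_TRAVEL_COLUMNS = ["cell_id", "hospital_id", "minutes"]
_STRATA_COLUMNS = ["municipality_id", "age_group", "sex", "population"]


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{name} is missing required column {col!r}")


def _validate_cells(cells: pd.DataFrame) -> None:
    _require_columns(cells, _CELL_COLUMNS, "cells table")
    if not np.issubdtype(np.asarray(cells["x_km"]).dtype, np.number):
        raise SchemaError("cells column 'x_km' must be numeric")
    if (cells["population"] < 0).any():
        raise ValidationError("cell population must be non-negative")
    if cells["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id")
    # each municipality belongs to exactly one district
    per_muni = cells.groupby("municipality_id")["district_id"].nunique()
    bad = per_muni[per_muni > 1]
    if len(bad):
        raise ValidationError(
            f"municipalities assigned to multiple districts: {list(bad.index)[:5]}"
        )


def _validate_hospitals(hospitals: pd.DataFrame) -> None:
    _require_columns(hospitals, _HOSPITAL_COLUMNS, "hospitals table")
    if hospitals["hospital_id"].duplicated().any():
        raise ValidationError("duplicate hospital_id")
    for col in hospitals.columns:
        if col.startswith(("beds_", "visits_")):
            if (hospitals[col] < 0).any():
                raise ValidationError(f"hospital column {col!r} must be non-negative")


def _validate_district_need(need: pd.DataFrame, cells: pd.DataFrame) -> None:
    _require_columns(need, _NEED_COLUMNS, "district need table")
    if (need["count"] < 0).any():
        raise ValidationError("district need counts must be non-negative")
    if need.duplicated(subset=["district_id", "age_group", "sex", "diagnosis"]).any():
        raise ValidationError("duplicate (district, age_group, sex, diagnosis) rows")
    known = set(need["district_id"])
    missing = set(cells["district_id"]) - known
    if missing:
        raise ValidationError(f"cells reference districts absent from the need table: {sorted(missing)[:5]}")


def _validate_travel(travel: pd.DataFrame, cells: pd.DataFrame, hospitals: pd.DataFrame) -> None:
    _require_columns(travel, _TRAVEL_COLUMNS, "travel time table")
    if not set(travel["cell_id"]).issubset(set(cells["cell_id"])):
        raise ValidationError("travel times reference unknown cell_id")
    if not set(travel["hospital_id"]).issubset(set(hospitals["hospital_id"])):
        raise ValidationError("travel times reference unknown hospital_id")


def read_scenario(directory: str | Path, max_catchment_min: float = 120.0) -> Scenario:
    """Load and validate a scenario from a directory of CSV files.

    Raises :class:`SchemaError` when a required column is absent and
    :class:`ValidationError` when a type invariant is violated.
    """
    directory = Path(directory)
    for fname in ("cells.csv", "hospitals.csv", "district_need.csv", "travel_times.csv"):
        if not (directory / fname).exists():
            raise FileNotFoundError(directory / fname)
    cells = pd.read_csv(directory / "cells.csv")
    hospitals = pd.read_csv(directory / "hospitals.csv")
    need = pd.read_csv(directory / "district_need.csv")
    travel = pd.read_csv(directory / "travel_times.csv")
    strata_path = directory / "municipality_strata.csv"
    strata = pd.read_csv(strata_path) if strata_path.exists() else None

    _validate_cells(cells)
    _validate_hospitals(hospitals)
    _validate_district_need(need, cells)
    _validate_travel(travel, cells, hospitals)
    if strata is not None:
        _require_columns(strata, _STRATA_COLUMNS, "municipality strata table")
        if (strata["population"] < 0).any():
            raise ValidationError("stratum populations must be non-negative")

    return Scenario(
        cells=cells,
        hospitals=hospitals,
        travel=TravelTimeMatrix(table=travel, max_catchment_min=max_catchment_min),
        district_need=need,
        municipality_strata=strata,
    )


def write_scenario(scenario: Scenario, directory: str | Path) -> None:
    """Write a scenario to CSV files readable by :func:`read_scenario`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scenario.cells.to_csv(directory / "cells.csv", index=False)
    scenario.hospitals.to_csv(directory / "hospitals.csv", index=False)
    scenario.district_need.to_csv(directory / "district_need.csv", index=False)
    scenario.travel.table.to_csv(directory / "travel_times.csv", index=False)
    if scenario.municipality_strata is not None:
        scenario.municipality_strata.to_csv(directory / "municipality_strata.csv", index=False)


def exclude_hospitals(
    hospitals: pd.DataFrame,
    diagnosis: str,
    specialty: str,
    min_counts: int = 10,
) -> pd.DataFrame:
    """Apply the hospital inclusion rules for one diagnosis.

    A hospital is included when it has capacity in the relevant specialty
    (``beds > 0``) and is relevant for the delivery of care for the
    diagnosis (``actual visits >= min_counts``, default 10).  Returns a
    copy with an ``included`` boolean column; the operation is idempotent.
    """
    bcol, vcol = beds_column(specialty), visits_column(diagnosis)
    if bcol not in hospitals.columns:
        raise KeyError(f"unknown specialty {specialty!r} (no column {bcol!r})")
    if vcol not in hospitals.columns:
        raise KeyError(f"unknown diagnosis {diagnosis!r} (no column {vcol!r})")
    out = hospitals.copy()
    out["included"] = (out[bcol] > 0) & (out[vcol] >= min_counts)
    return out


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """Tunable parameters of the prediction pipeline.

    ``decays`` maps each FCA method to its decay family; the defaults are
    the method-specific forms: iFCA a logistic sigmoid centred at the
    60-min mean effective catchment, M2SFCA the downward log-logistic with
    alpha = 13.39 / beta = 1.89, and E2SFCA the four-zone fast-decay
    Gaussian step.
    """

    decays: dict = field(
        default_factory=lambda: {
            "ifca": DecaySpec.logistic(mu=60.0, s=6.0),
            "m2sfca": DecaySpec.log_logistic(alpha=13.39, beta=1.89),
            "e2sfca": DecaySpec.gaussian_zonal(),
        }
    )
    max_catchment_min: float = 120.0
    effective_threshold: float = 0.01
    min_counts: int = 10
    variant: str = "decay_consistent"
    specialty_of: dict = field(default_factory=dict)  # diagnosis -> specialty
    bands: tuple = (0.05, 0.10, 0.15)
    seed: int = 0

    def decay_for(self, method: str) -> DecaySpec:
        try:
            return self.decays[method]
        except KeyError:
            raise KeyError(f"no decay configured for method {method!r}") from None


def _decay_from_dict(d: dict) -> DecaySpec:
    family = d.get("family")
    if family == "logistic":
        return DecaySpec.logistic(mu=float(d.get("mu", 60.0)), s=float(d.get("s", 6.0)))
    if family == "log_logistic":
        return DecaySpec.log_logistic(
            alpha=float(d.get("alpha", 13.39)), beta=float(d.get("beta", 1.89))
        )
    if family == "gaussian_zonal":
        return DecaySpec.gaussian_zonal(
            zone_bounds=d.get("zone_bounds", (30.0, 60.0, 90.0, 120.0)),
            zone_weights=d.get("zone_weights"),
        )
    raise SchemaError(f"unknown decay family in config: {family!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a parsed YAML mapping."""
    cfg = PipelineConfig()
    for method, d in (raw.get("decay") or {}).items():
        cfg.decays[method] = _decay_from_dict(d)
    catch = raw.get("catchment") or {}
    cfg.max_catchment_min = float(catch.get("max_min", cfg.max_catchment_min))
    cfg.effective_threshold = float(catch.get("effective_threshold", cfg.effective_threshold))
    excl = raw.get("exclusion") or {}
    cfg.min_counts = int(excl.get("min_counts", cfg.min_counts))
    cfg.variant = raw.get("variant", cfg.variant)
    cfg.specialty_of = dict(raw.get("specialty_of") or cfg.specialty_of)
    cfg.bands = tuple(raw.get("bands", cfg.bands))
    cfg.seed = int(raw.get("seed", cfg.seed))
    return cfg
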