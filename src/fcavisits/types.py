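"""Shared domain containers.

The in-memory representation is deliberately tabular: cells and hospitals
live in pandas DataFrames using the same column conventions as the on-disk
CSV formats, and the travel-time matrix is a long-form sparse table
restricted to the hard catchment.  Coordinates are planar kilometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TravelTimeMatrix",
    "Scenario",
    "WeightMatrix",
    "AccessibilityIndex",
    "PredictionResult",
    "need_column",
    "beds_column",
    "visits_column",
]


def need_column(diagnosis: str) -> str:
    return f"need_{diagnosis}"


def beds_column(specialty: str) -> str:
    return f"beds_{specialty}"


def visits_column(diagnosis: str) -> str:
    return f"visits_{diagnosis}"


@dataclass
class TravelTimeMatrix:
    """Sparse origin–destination travel times in minutes.

    Only pairs within the hard catchment (``minutes <= max_catchment_min``)
    are stored; absent pairs are unreachable.
    """

    table: pd.DataFrame  # columns: cell_id, hospital_id, minutes
    max_catchment_min: float = 120.0

    def __post_init__(self):
        required = {"cell_id", "hospital_id", "minutes"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"travel time table missing columns: {sorted(missing)}")
        m = self.table["minutes"].to_numpy(dtype=float)
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("travel times must be finite and non-negative")
        if np.any(m > self.max_catchment_min):
            raise ValueError(
                f"travel times beyond the {self.max_catchment_min}-min catchment must not be stored"
            )

    @classmethod
    def from_dense(
        cls,
        minutes: np.ndarray,
        cell_ids: np.ndarray,
        hospital_ids: np.ndarray,
        max_catchment_min: float = 120.0,
    ) -> "TravelTimeMatrix":
        """Build from a dense (n_cells, n_hospitals) minutes array, dropping
        pairs beyond the catchment."""
        ci, hi = np.nonzero(minutes <= max_catchment_min)
        table = pd.DataFrame(
            {
                "cell_id": np.asarray(cell_ids)[ci],
                "hospital_id": np.asarray(hospital_ids)[hi],
                "minutes": minutes[ci, hi],
            }
        )
        return cls(table=table, max_catchment_min=max_catchment_min)

    def dense(self, cell_ids, hospital_ids) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(minutes, reachable)`` dense arrays aligned to the given id
        orders; unreachable pairs hold ``inf`` minutes and ``False``."""
        cell_ids = np.asarray(cell_ids)
        hospital_ids = np.asarray(hospital_ids)
        cpos = {c: i for i, c in enumerate(cell_ids)}
        hpos = {h: j for j, h in enumerate(hospital_ids)}
        minutes = np.full((len(cell_ids), len(hospital_ids)), np.inf)
        tc = self.table["cell_id"].to_numpy()
        th = self.table["hospital_id"].to_numpy()
        tm = self.table["minutes"].to_numpy(dtype=float)
        for c, h, m in zip(tc, th, tm):
            i = cpos.get(c)
            j = hpos.get(h)
            if i is not None and j is not None:
                minutes[i, j] = m
        return minutes, np.isfinite(minutes)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class Scenario:
    """One fully loaded study region.

    ``cells`` carries the population grid with the municipality/district
    hierarchy (and, once need has been disaggregated, ``need_<diagnosis>``
    columns).  ``hospitals`` carries ``beds_<specialty>`` and
    ``visits_<diagnosis>`` columns.  ``municipality_strata`` holds the
    age/sex-stratified municipality populations the proportional
    disaggregation needs.
    """

    cells: pd.DataFrame
    hospitals: pd.DataFrame
    travel: TravelTimeMatrix
    district_need: pd.DataFrame
    municipality_strata: pd.DataFrame | None = None

    @property
    def diagnoses(self) -> list[str]:
        return sorted(self.district_need["diagnosis"].unique())

    @property
    def specialties(self) -> list[str]:
        return sorted(
            c[len("beds_") :] for c in self.hospitals.columns if c.startswith("beds_")
        )

    def need(self, diagnosis: str) -> pd.Series:
        col = need_column(diagnosis)
        if col not in self.cells.columns:
            raise KeyError(
                f"cells carry no need column for {diagnosis!r}; run need disaggregation first"
            )
        return pd.Series(
            self.cells[col].to_numpy(dtype=float), index=self.cells["cell_id"].to_numpy()
        )


@dataclass
class WeightMatrix:
    """Per-(cell, hospital) visit weights W in [0, 1] for one method."""

    weights: np.ndarray  # dense (n_cells, n_hospitals)
    cell_ids: np.ndarray
    hospital_ids: np.ndarray
    method: str

    def row_sums(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class AccessibilityIndex:
    """Accessibility index AI per cell plus its per-hospital partials."""

    ai: np.ndarray  # (n_cells,)
    partials: np.ndarray  # (n_cells, n_hospitals), zero outside catchment
    cell_ids: np.ndarray
    hospital_ids: np.ndarray
    method: str
    variant: str  # "as_printed" | "decay_consistent"


@dataclass
class PredictionResult:
    """Predicted visits per hospital for one method and diagnosis."""

    method: str
    diagnosis: str
    visits: pd.Series  # hospital_id -> predicted visits
    factorized: bool = False
    scale_factor: float = 1.0
    attractiveness_source: str = "beds"

    def to_frame(self, actual: pd.Series | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "hospital_id": self.visits.index,
                "predicted_visits": self.visits.to_numpy(dtype=float),
            }
        )
        if actual is not None:
            out["actual_visits"] = actual.reindex(self.visits.index).to_numpy()
        out["method"] = self.method
        out["diagnosis"] = self.diagnosis
        out["attractiveness"] = self.attractiveness_source
        out["scale_factor"] = self.scale_factor
        return out
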