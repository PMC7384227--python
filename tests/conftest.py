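from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fcavisits.synthetic import DiagnosisSpec, ScenarioSpec, generate_scenario
from fcavisits.types import Scenario, TravelTimeMatrix


def random_instance(rng: np.random.Generator, n_cells: int, n_hospitals: int):
    """A small random instance for oracle-equivalence checks.

    Returns ``(cells, hospitals, travel, P, S, d)`` where ``d`` is the
    sparse dict-of-pairs view the nested-loop oracles consume.  Every
    cell and every hospital keeps at least one in-catchment pair, all
    need and attractiveness values are strictly positive, and travel
    times stay below the catchment so all decay weights are positive.
    """
    P = rng.uniform(0.5, 10.0, n_cells)
    S = rng.uniform(1.0, 100.0, n_hospitals)
    minutes = rng.uniform(1.0, 100.0, (n_cells, n_hospitals))
    keep = rng.random((n_cells, n_hospitals)) > 0.3
    for i in range(n_cells):  # keep the instance fully connected
        if not keep[i].any():
            keep[i, rng.integers(n_hospitals)] = True
    for j in range(n_hospitals):
        if not keep[:, j].any():
            keep[rng.integers(n_cells), j] = True
    minutes = np.where(keep, minutes, np.inf)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "x_km": rng.uniform(0, 50, n_cells),
            "y_km": rng.uniform(0, 50, n_cells),
            "population": rng.uniform(10, 1000, n_cells),
            "municipality_id": 0,
            "district_id": 0,
        }
    )
    hospitals = pd.DataFrame(
        {
            "hospital_id": np.arange(n_hospitals),
            "x_km": rng.uniform(0, 50, n_hospitals),
            "y_km": rng.uniform(0, 50, n_hospitals),
        }
    )
    travel = TravelTimeMatrix.from_dense(
        minutes, cells["cell_id"].to_numpy(), hospitals["hospital_id"].to_numpy()
    )
    d = {
        (int(r.cell_id), int(r.hospital_id)): float(r.minutes)
        for r in travel.table.itertuples()
    }
    return cells, hospitals, travel, P, S, d


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture(scope="session")
def small_synthetic():
    """A 10x10 region with simulated visits, shared across tests."""
    spec = ScenarioSpec(
        grid_rows=10,
        grid_cols=10,
        n_districts=4,
        municipalities_per_district=4,
        n_hospitals=5,
        diagnoses=(
            DiagnosisSpec(name="I48", base_rate=0.05, gradient_axis="ns"),
            DiagnosisSpec(name="I50", base_rate=0.08, gradient_axis="ew"),
        ),
        seed=7,
    )
    return generate_scenario(spec)
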