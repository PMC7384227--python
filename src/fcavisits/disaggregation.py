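"""Small-area disaggregation of district-level diagnosis counts.

District-level diagnosis counts stratified by 5-year age group and sex are
split to municipalities proportionally to each stratum's municipality
population, summed over strata, and then spread evenly over the 1-km² grid
cells of each municipality.  The result is the per-cell need for care
P_x consumed by the prediction step.  All allocations stay real-valued so
that totals are conserved exactly; integer realizations belong to the
visit simulator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import Scenario, need_column

__all__ = [
    "AllocationError",
    "AGE_BANDS",
    "SEXES",
    "disaggregate_to_municipality",
    "assign_to_grid",
    "normalize_per_capita",
    "disaggregate_need",
    "need_surface",
]


class AllocationError(ValueError):
    """A count cannot be allocated (empty municipality, zero-population stratum...)."""


#: Eighteen 5-year age bands (open-ended top band).
AGE_BANDS = tuple(
    ["1-4"] + [f"{lo}-{lo + 4}" for lo in range(5, 85, 5)] + ["85+"]
)
SEXES = ("male", "female")


def disaggregate_to_municipality(
    district_need: pd.DataFrame,
    municipality_strata: pd.DataFrame,
    municipality_district: pd.Series | dict,
) -> pd.DataFrame:
    """Split district counts to municipalities proportionally by stratum population.

    For every (district, age group, sex, diagnosis) count, the count is
    divided across the district's municipalities in proportion to that
    stratum's municipality population, then summed over strata.  District
    totals are conserved exactly.

    Parameters
    ----------
    district_need:
        Rows (district_id, age_group, sex, diagnosis, count).
    municipality_strata:
        Rows (municipality_id, age_group, sex, population).
    municipality_district:
        Mapping municipality_id -> district_id.

    Returns
    -------
    DataFrame with rows (municipality_id, diagnosis, count).
    """
    md = pd.Series(municipality_district)
    strata = municipality_strata.copy()
    unknown = set(strata["municipality_id"]) - set(md.index)
    if unknown:
        raise AllocationError(f"strata reference municipalities without a district: {sorted(unknown)[:5]}")
    strata["district_id"] = strata["municipality_id"].map(md)

    # stratum share of each municipality within its district
    totals = strata.groupby(["district_id", "age_group", "sex"])["population"].transform("sum")
    strata = strata.assign(_district_pop=totals)

    merged = district_need.merge(
        strata,
        on=["district_id", "age_group", "sex"],
        how="inner",
    )
    # a district stratum with a nonzero count but zero population cannot be allocated
    bad = merged[(merged["count"] > 0) & (merged["_district_pop"] == 0)]
    if len(bad):
        row = bad.iloc[0]
        raise AllocationError(
            "cannot allocate nonzero count over zero population: "
            f"district {row['district_id']}, stratum ({row['age_group']}, {row['sex']})"
        )
    merged = merged[merged["_district_pop"] > 0]
    merged["allocated"] = merged["count"] * merged["population"] / merged["_district_pop"]
    out = (
        merged.groupby(["municipality_id", "diagnosis"], as_index=False)["allocated"]
        .sum()
        .rename(columns={"allocated": "count"})
    )
    return out


def assign_to_grid(muni_counts: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Spread municipality counts evenly over the municipality's grid cells.

    Each cell receives ``count / n_cells`` (real-valued).  Returns a copy
    of ``cells`` with one ``need_<diagnosis>`` column per diagnosis.
    """
    n_cells = cells.groupby("municipality_id")["cell_id"].size()
    empty = set(muni_counts["municipality_id"]) - set(n_cells.index)
    if empty:
        raise AllocationError(f"municipalities with counts but no grid cells: {sorted(empty)[:5]}")
    out = cells.copy()
    for diagnosis, grp in muni_counts.groupby("diagnosis"):
        per_cell = (grp.set_index("municipality_id")["count"] / n_cells).fillna(0.0)
        out[need_column(diagnosis)] = (
            out["municipality_id"].map(per_cell).fillna(0.0).to_numpy(dtype=float)
        )
    return out


def normalize_per_capita(cells: pd.DataFrame, diagnosis: str) -> pd.Series:
    """Per-capita need rate P_x / population per cell.

    Cells with zero population get NaN (flagged missing), never infinity.
    """
    col = need_column(diagnosis)
    if col not in cells.columns:
        raise KeyError(f"cells carry no need column for {diagnosis!r}")
    pop = cells["population"].to_numpy(dtype=float)
    need = cells[col].to_numpy(dtype=float)
    rate = np.where(pop > 0, need / np.where(pop > 0, pop, 1.0), np.nan)
    return pd.Series(rate, index=cells["cell_id"].to_numpy(), name="rate")


def disaggregate_need(scenario: Scenario) -> Scenario:
    """Run the full district → municipality → grid chain on a scenario.

    Returns a new scenario whose cells carry ``need_<diagnosis>`` columns.
    Requires ``municipality_strata`` to be present.
    """
    if scenario.municipality_strata is None:
        raise AllocationError("scenario carries no municipality_strata table")
    md = (
        scenario.cells.drop_duplicates("municipality_id")
        .set_index("municipality_id")["district_id"]
    )
    muni_counts = disaggregate_to_municipality(
        scenario.district_need, scenario.municipality_strata, md
    )
    cells = assign_to_grid(muni_counts, scenario.cells)
    return Scenario(
        cells=cells,
        hospitals=scenario.hospitals,
        travel=scenario.travel,
        district_need=scenario.district_need,
        municipality_strata=scenario.municipality_strata,
    )


def need_surface(cells: pd.DataFrame, diagnoses: list[str]) -> pd.DataFrame:
    """Long-form need surface (cell_id, diagnosis, need, rate) for export."""
    frames = []
    for diagnosis in diagnoses:
        rate = normalize_per_capita(cells, diagnosis)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cells["cell_id"].to_numpy(),
                    "diagnosis": diagnosis,
                    "need": cells[need_column(diagnosis)].to_numpy(dtype=float),
                    "rate": rate.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
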