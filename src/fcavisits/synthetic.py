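"""Synthetic study regions with known ground truth.

The generator emulates the structure of the real inputs the prediction
pipeline expects — a rectangular grid of 1-km² cells with heterogeneous
(log-normal) population, a district → municipality → cell hierarchy,
hospitals with log-normal bed counts, an origin–destination travel-time
matrix from plane geometry, and age/sex-stratified district diagnosis
counts — plus ground-truth hospital visits drawn from a known
distance-decayed Huff choice model, so recovery experiments can compare
predictions against a truth that real registry data never reveals.

Two deliberate realism choices:

* The spatial need gradient (the north–south / east–west disease-burden
  patterns seen in normalized count maps) is applied at *district* level,
  so the proportional disaggregation's own assumption holds exactly and
  the pipeline can be validated against the known cell-level need.
* True hospital attractiveness is ``beds × log-normal quality factor``:
  beds are an informative but imperfect proxy, which is precisely the
  regime the method evaluation is about.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import DecaySpec
from .disaggregation import AGE_BANDS, SEXES
from .io import write_scenario
from .types import Scenario, TravelTimeMatrix, beds_column, need_column, visits_column

__all__ = [
    "DiagnosisSpec",
    "ScenarioSpec",
    "SyntheticScenario",
    "SimulationError",
    "generate_scenario",
    "simulate_visits",
    "make_benchmark_suite",
]


class SimulationError(RuntimeError):
    """Ground-truth simulation cannot proceed (e.g. unreachable need)."""


#: Relative population share per 5-year age band (normalized at use);
#: a broadly European pyramid with a mid-life bulge.
BASE_PYRAMID = np.array(
    [3.7, 4.5, 4.7, 4.9, 5.3, 6.1, 6.5, 6.3, 5.9, 6.3, 7.7, 7.5, 6.5, 5.5, 4.5, 4.3, 3.6, 2.7]
)


@dataclass(frozen=True)
class DiagnosisSpec:
    """Statistical model of one diagnosis' need for care.

    ``base_rate`` is the population-weighted mean expected cases per
    person-year; ``age_slope`` the log-linear rise in relative risk per
    5-year band (cardiovascular-style diagnoses rise steeply with age);
    ``sex_ratio`` the male:female relative risk; ``gradient_axis`` the
    spatial disease-burden gradient ("ns", "ew", or None) of strength
    ``gradient_strength`` across the study region, applied at district
    level.
    """

    name: str
    specialty: str = "internal_medicine"
    base_rate: float = 0.005
    age_slope: float = 0.3
    sex_ratio: float = 1.2
    gradient_axis: str | None = "ns"
    gradient_strength: float = 0.5


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic study region.

    The defaults describe the canonical test region: a 30×30-km grid
    (900 one-km² cells), 9 districts of 4 municipalities each, 25
    hospitals, log-normal cell populations averaging ≈245 persons/km²,
    and a slow (non-emergency) log-logistic choice decay with a 30-min
    half-weight travel time generating the ground-truth visits.
    """

    grid_rows: int = 30
    grid_cols: int = 30
    n_districts: int = 9
    municipalities_per_district: int = 4
    n_hospitals: int = 25
    pop_meanlog: float = 5.0
    pop_sdlog: float = 1.0
    beds_meanlog: float = 4.0
    beds_sdlog: float = 0.6
    quality_sdlog: float = 0.5  # unmodelled attractiveness noise on top of beds
    pyramid_jitter_sdlog: float = 0.15
    pace_min_per_km: float = 1.0
    jitter_sdlog: float = 0.1  # multiplicative travel-time noise
    max_catchment_min: float = 120.0
    choice_decay: DecaySpec = field(
        default_factory=lambda: DecaySpec.log_logistic(alpha=30.0, beta=1.89)
    )
    diagnoses: tuple[DiagnosisSpec, ...] = (
        DiagnosisSpec(name="I48", base_rate=0.004, gradient_axis="ns"),
        DiagnosisSpec(name="I50", base_rate=0.006, gradient_axis="ew"),
    )
    seed: int = 0


@dataclass
class SyntheticScenario:
    """A generated scenario together with its ground truth."""

    scenario: Scenario
    true_need: pd.DataFrame  # cell_id + need_<diagnosis> columns (the generating truth)
    true_attractiveness: pd.DataFrame  # hospital_id + attr_<diagnosis> columns
    spec: ScenarioSpec


def _bands(n: int, k: int) -> np.ndarray:
    """Map indices 0..n-1 to k contiguous near-equal bands."""
    sizes = [len(a) for a in np.array_split(np.arange(n), k)]
    return np.repeat(np.arange(k), sizes)


def _near_square(n: int) -> tuple[int, int]:
    """Factor n as r*c with r <= c and r the largest divisor <= sqrt(n)."""
    r = int(math.isqrt(n))
    while n % r:
        r -= 1
    return r, n // r


def _stratum_rates(diag: DiagnosisSpec) -> pd.Series:
    """Expected cases per person-year per (age band, sex) stratum.

    Scaled so that the pyramid-weighted mean equals ``base_rate``.
    """
    age_mult = np.exp(diag.age_slope * np.arange(len(AGE_BANDS)))
    sex_mult = {"male": diag.sex_ratio, "female": 1.0}
    shares = BASE_PYRAMID / BASE_PYRAMID.sum()
    mean = sum(
        0.5 * shares[i] * age_mult[i] * sex_mult[sex]
        for i in range(len(AGE_BANDS))
        for sex in SEXES
    )
    rates = {
        (AGE_BANDS[i], sex): diag.base_rate * age_mult[i] * sex_mult[sex] / mean
        for i in range(len(AGE_BANDS))
        for sex in SEXES
    }
    return pd.Series(rates)


def generate_scenario(spec: ScenarioSpec, seed: int | None = None) -> SyntheticScenario:
    """Generate a complete synthetic scenario (deterministic per seed).

    The district diagnosis table is built by aggregating the known
    cell-level truth upward, so the disaggregation stage can be tested
    against that truth.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_cells = spec.grid_rows * spec.grid_cols
    if spec.n_hospitals > n_cells:
        raise ValueError("more hospitals than grid cells")

    # --- grid and hierarchy (0-based row-major cell ids) ---
    rows, cols = np.divmod(np.arange(n_cells), spec.grid_cols)
    dr, dc = _near_square(spec.n_districts)
    mr, mc = _near_square(spec.municipalities_per_district)
    drow, dcol = _bands(spec.grid_rows, dr)[rows], _bands(spec.grid_cols, dc)[cols]
    district_id = drow * dc + dcol
    # municipality sub-blocks inside each district band
    row_starts = np.concatenate([[0], np.cumsum([len(a) for a in np.array_split(np.arange(spec.grid_rows), dr)])])
    col_starts = np.concatenate([[0], np.cumsum([len(a) for a in np.array_split(np.arange(spec.grid_cols), dc)])])
    mrow = np.empty(n_cells, dtype=int)
    mcol = np.empty(n_cells, dtype=int)
    for b in range(dr):
        sel = drow == b
        size = row_starts[b + 1] - row_starts[b]
        mrow[sel] = _bands(size, mr)[rows[sel] - row_starts[b]]
    for b in range(dc):
        sel = dcol == b
        size = col_starts[b + 1] - col_starts[b]
        mcol[sel] = _bands(size, mc)[cols[sel] - col_starts[b]]
    municipality_id = district_id * spec.municipalities_per_district + (mrow * mc + mcol)

    population = rng.lognormal(spec.pop_meanlog, spec.pop_sdlog, n_cells)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "x_km": cols + 0.5,
            "y_km": rows + 0.5,
            "population": population,
            "municipality_id": municipality_id,
            "district_id": district_id,
        }
    )

    # --- age/sex-stratified municipality populations ---
    muni_ids = np.unique(municipality_id)
    muni_pop = cells.groupby("municipality_id")["population"].sum()
    shares = BASE_PYRAMID / BASE_PYRAMID.sum()
    strata_rows = []
    for m in muni_ids:
        noisy = shares * rng.lognormal(0.0, spec.pyramid_jitter_sdlog, len(shares))
        noisy = noisy / noisy.sum()
        for i, band in enumerate(AGE_BANDS):
            frac_male = 0.5
            for sex, frac in (("male", frac_male), ("female", 1 - frac_male)):
                strata_rows.append((m, band, sex, muni_pop[m] * noisy[i] * frac))
    strata = pd.DataFrame(
        strata_rows, columns=["municipality_id", "age_group", "sex", "population"]
    )

    # --- need: district-level gradient × stratum rates, aggregated upward ---
    muni_district = cells.drop_duplicates("municipality_id").set_index("municipality_id")[
        "district_id"
    ]
    dcent = cells.groupby("district_id")[["x_km", "y_km"]].mean()
    true_need = pd.DataFrame({"cell_id": cells["cell_id"]})
    need_table_rows = []
    n_cells_per_muni = cells.groupby("municipality_id")["cell_id"].size()
    for diag in spec.diagnoses:
        rates = _stratum_rates(diag)
        if diag.gradient_axis == "ns":
            t = dcent["y_km"] / (spec.grid_rows or 1)
        elif diag.gradient_axis == "ew":
            t = dcent["x_km"] / (spec.grid_cols or 1)
        else:
            t = pd.Series(0.5, index=dcent.index)
        gradient = 1.0 + diag.gradient_strength * (2.0 * t - 1.0)
        # municipality expected counts, then even split to cells
        muni_counts = pd.Series(0.0, index=muni_ids, dtype=float)
        s = strata.set_index(["municipality_id", "age_group", "sex"])["population"]
        for (m, band, sex), pop in s.items():
            g = gradient[muni_district[m]]
            contrib = pop * rates[(band, sex)] * g
            muni_counts[m] += contrib
            need_table_rows.append((muni_district[m], band, sex, diag.name, contrib))
        per_cell = muni_counts / n_cells_per_muni
        true_need[need_column(diag.name)] = cells["municipality_id"].map(per_cell).to_numpy()
    district_need = (
        pd.DataFrame(
            need_table_rows,
            columns=["district_id", "age_group", "sex", "diagnosis", "count"],
        )
        .groupby(["district_id", "age_group", "sex", "diagnosis"], as_index=False)["count"]
        .sum()
    )

    # --- hospitals ---
    host_cells = np.sort(rng.choice(n_cells, size=spec.n_hospitals, replace=False))
    specialties = sorted({d.specialty for d in spec.diagnoses})
    hospitals = pd.DataFrame(
        {
            "hospital_id": np.arange(spec.n_hospitals),
            "x_km": cells.loc[host_cells, "x_km"].to_numpy(),
            "y_km": cells.loc[host_cells, "y_km"].to_numpy(),
        }
    )
    for sp in specialties:
        beds = np.maximum(1, np.round(rng.lognormal(spec.beds_meanlog, spec.beds_sdlog, spec.n_hospitals)))
        hospitals[beds_column(sp)] = beds.astype(int)
    quality = rng.lognormal(0.0, spec.quality_sdlog, spec.n_hospitals)

    # --- travel times: plane geometry × pace × multiplicative jitter ---
    dx = cells["x_km"].to_numpy()[:, None] - hospitals["x_km"].to_numpy()[None, :]
    dy = cells["y_km"].to_numpy()[:, None] - hospitals["y_km"].to_numpy()[None, :]
    minutes = np.hypot(dx, dy) * spec.pace_min_per_km
    minutes *= rng.lognormal(0.0, spec.jitter_sdlog, minutes.shape)
    travel = TravelTimeMatrix.from_dense(
        minutes, cells["cell_id"].to_numpy(), hospitals["hospital_id"].to_numpy(),
        max_catchment_min=spec.max_catchment_min,
    )

    # --- ground-truth visits from the Huff choice model ---
    true_attr = pd.DataFrame({"hospital_id": hospitals["hospital_id"]})
    for diag in spec.diagnoses:
        S_true = hospitals[beds_column(diag.specialty)].to_numpy(dtype=float) * quality
        true_attr[f"attr_{diag.name}"] = S_true
        visits = simulate_visits(
            true_need[need_column(diag.name)].to_numpy(),
            travel,
            spec.choice_decay,
            S_true,
            rng,
            cell_ids=cells["cell_id"].to_numpy(),
            hospital_ids=hospitals["hospital_id"].to_numpy(),
        )
        hospitals[visits_column(diag.name)] = visits.to_numpy().astype(int)

    scenario = Scenario(
        cells=cells,
        hospitals=hospitals,
        travel=travel,
        district_need=district_need,
        municipality_strata=strata,
    )
    return SyntheticScenario(
        scenario=scenario, true_need=true_need, true_attractiveness=true_attr, spec=spec
    )


def simulate_visits(
    cell_need: np.ndarray,
    travel: TravelTimeMatrix,
    choice: DecaySpec,
    S: np.ndarray,
    rng: np.random.Generator,
    cell_ids: np.ndarray | None = None,
    hospital_ids: np.ndarray | None = None,
) -> pd.Series:
    """Draw integer ground-truth visits from a distance-decayed Huff model.

    Each cell's real-valued need is realized as a Poisson count, then
    allocated over reachable hospitals by a multinomial draw with Huff
    probabilities ``S_y f(d_xy) / sum_z S_z f(d_xz)``.  The total visits
    equal the total realized need exactly.
    """
    cell_need = np.asarray(cell_need, dtype=float)
    if cell_ids is None:
        cell_ids = np.arange(len(cell_need))
    if hospital_ids is None:
        hospital_ids = np.unique(travel.table["hospital_id"])
    S = np.asarray(S, dtype=float)
    minutes, reachable = travel.dense(cell_ids, hospital_ids)
    F = np.zeros_like(minutes)
    if reachable.any():
        F[reachable] = np.asarray(choice.weight(minutes[reachable]))
    probs = F * S[None, :]
    row_tot = probs.sum(axis=1)

    realized = rng.poisson(cell_need)
    bad = (realized > 0) & (row_tot <= 0)
    if bad.any():
        raise SimulationError(
            f"need at cells with no reachable hospital: {list(np.asarray(cell_ids)[bad][:10])}"
        )
    visits = np.zeros(len(hospital_ids), dtype=np.int64)
    for i in np.nonzero(realized > 0)[0]:
        visits += rng.multinomial(realized[i], probs[i] / row_tot[i])
    return pd.Series(visits, index=hospital_ids)


def make_benchmark_suite(seed: int = 0, outdir: str | Path | None = None) -> dict:
    """Canonical small fixtures used across the test suite.

    Returns a dict of named :class:`SyntheticScenario` (or bare
    :class:`Scenario` for the hand-built tie case); with ``outdir`` set,
    each is also written under ``outdir/<name>/`` in the standard file
    formats.
    """
    # higher base rates keep hospitals above the 10-visit inclusion floor
    small_diags = (
        DiagnosisSpec(name="I48", base_rate=0.05, gradient_axis="ns"),
        DiagnosisSpec(name="I50", base_rate=0.08, gradient_axis="ew"),
    )
    suite: dict[str, object] = {}
    suite["grid_1x1_single_hospital"] = generate_scenario(
        ScenarioSpec(
            grid_rows=1, grid_cols=1, n_districts=1, municipalities_per_district=1,
            n_hospitals=1, diagnoses=small_diags, seed=seed,
        )
    )
    suite["grid_2x2"] = generate_scenario(
        ScenarioSpec(
            grid_rows=2, grid_cols=2, n_districts=1, municipalities_per_district=2,
            n_hospitals=2, diagnoses=small_diags, seed=seed + 1,
        )
    )
    suite["grid_10x10"] = generate_scenario(
        ScenarioSpec(
            grid_rows=10, grid_cols=10, n_districts=4, municipalities_per_district=4,
            n_hospitals=5, diagnoses=small_diags, seed=seed + 2,
        )
    )
    suite["tie_equidistant"] = _tie_scenario()
    if outdir is not None:
        outdir = Path(outdir)
        for name, item in suite.items():
            scenario = item.scenario if isinstance(item, SyntheticScenario) else item
            write_scenario(scenario, outdir / name)
    return suite


def _tie_scenario() -> Scenario:
    """One cell, two identical hospitals at exactly equal travel time."""
    cells = pd.DataFrame(
        {
            "cell_id": [0], "x_km": [0.5], "y_km": [0.5], "population": [1000.0],
            "municipality_id": [0], "district_id": [0],
        }
    )
    hospitals = pd.DataFrame(
        {
            "hospital_id": [0, 1], "x_km": [10.5, 10.5], "y_km": [0.5, 0.5],
            "beds_internal_medicine": [50, 50], "visits_I48": [100, 100],
        }
    )
    travel = TravelTimeMatrix(
        table=pd.DataFrame(
            {"cell_id": [0, 0], "hospital_id": [0, 1], "minutes": [10.0, 10.0]}
        )
    )
    district_need = pd.DataFrame(
        {
            "district_id": [0], "age_group": [AGE_BANDS[10]], "sex": ["female"],
            "diagnosis": ["I48"], "count": [200.0],
        }
    )
    strata = pd.DataFrame(
        {
            "municipality_id": [0], "age_group": [AGE_BANDS[10]], "sex": ["female"],
            "population": [1000.0],
        }
    )
    return Scenario(
        cells=cells, hospitals=hospitals, travel=travel,
        district_need=district_need, municipality_strata=strata,
    )
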