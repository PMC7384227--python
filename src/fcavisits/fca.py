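"""Predicted hospital visits under floating catchment area (FCA) methods.

All methods share the same conceptual model: the predicted visits at
hospital y are the decay- and competition-weighted sum of the need for
care P_x over all population locations x within the hard catchment,

    V_y = sum_x  W(x, y) * P_x,

and differ only in how the weight W is built:

* **iFCA** — W = f(d_xy) multiplied by a Huff choice probability
  (attractiveness times decay, normalized over the competing hospitals
  reachable from x).
* **M2SFCA / E2SFCA** — W is the ratio of a hospital's *partial*
  accessibility index to the cell's total accessibility index AI.  The
  M2SFCA numerator squares the decay (penalizing suboptimally placed
  capacity); the E2SFCA numerator uses a single decay factor.
* **closest provider** — benchmark: all of a cell's need goes to its
  nearest included hospital.

Predictions are finally *factorized*: rescaled by a single factor so that
the predicted total matches the actual total over the included hospitals.

For the partial indices two variants exist.  ``as_printed`` follows the
published partial-index formulas literally (single decay for M2SFCA, no
decay for E2SFCA); ``decay_consistent`` (default) takes the partial to be
the exact per-hospital summand of the AI, so partials sum to the AI and
the resulting weights are row-normalized probabilities.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .decay import DecaySpec
from .io import PipelineConfig, exclude_hospitals
from .types import (
    AccessibilityIndex,
    PredictionResult,
    Scenario,
    TravelTimeMatrix,
    WeightMatrix,
    beds_column,
    visits_column,
)

__all__ = [
    "IsolatedHospitalError",
    "FactorizationError",
    "huff_probabilities",
    "huff_matrix",
    "ifca_weights",
    "compute_ai",
    "weights_from_partials",
    "predict_visits",
    "closest_provider_predict",
    "factorize",
    "run_method",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("ifca", "m2sfca", "e2sfca", "closest")


class IsolatedHospitalError(ValueError):
    """A hospital's demand denominator is zero although cells can reach it."""


class FactorizationError(ValueError):
    """The predicted total is zero and cannot be rescaled."""


def _decay_matrix(
    minutes: np.ndarray, reachable: np.ndarray, decay: DecaySpec
) -> np.ndarray:
    """Decay weights f(d_xy) on reachable pairs, exactly zero elsewhere."""
    f = np.zeros_like(minutes)
    if reachable.any():
        f[reachable] = np.asarray(decay.weight(minutes[reachable]))
    return f


def huff_probabilities(S: np.ndarray, fvals: np.ndarray) -> np.ndarray:
    """Huff choice probabilities for one cell.

    ``S`` and ``fvals`` are aligned vectors of attractiveness and decay
    weight over the hospitals reachable from the cell; the probability of
    hospital y is ``S_y f_y / sum_z S_z f_z``.  Raises when every product
    is zero (degenerate cell).
    """
    S = np.asarray(S, dtype=float)
    fvals = np.asarray(fvals, dtype=float)
    num = S * fvals
    denom = num.sum()
    if denom <= 0:
        raise ValueError("degenerate cell: all attractiveness-decay products are zero")
    return num / denom


def huff_matrix(S: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Huff probabilities for all cells.

    Returns ``(H, degenerate)`` where degenerate rows (no positive
    attractiveness-decay product) are all-zero rather than raising; the
    flag vector identifies them so callers can log the cells.
    """
    num = F * S[np.newaxis, :]
    denom = num.sum(axis=1, keepdims=True)
    degenerate = denom[:, 0] <= 0
    H = np.divide(num, denom, out=np.zeros_like(num), where=~degenerate[:, np.newaxis])
    return H, degenerate


def ifca_weights(
    cells: pd.DataFrame,
    hospitals: pd.DataFrame,
    S: np.ndarray,
    travel: TravelTimeMatrix,
    decay: DecaySpec,
) -> WeightMatrix:
    """iFCA weights: W(x,y) = f(d_xy) * Huff probability of y from x."""
    cell_ids = cells["cell_id"].to_numpy()
    hospital_ids = hospitals["hospital_id"].to_numpy()
    minutes, reachable = travel.dense(cell_ids, hospital_ids)
    F = _decay_matrix(minutes, reachable, decay)
    H, degenerate = huff_matrix(np.asarray(S, dtype=float), F)
    if degenerate.any():
        logger.info(
            "iFCA: %d degenerate cells emit no visits: %s",
            int(degenerate.sum()),
            list(cell_ids[degenerate][:10]),
        )
    return WeightMatrix(weights=F * H, cell_ids=cell_ids, hospital_ids=hospital_ids, method="ifca")


def compute_ai(
    cells: pd.DataFrame,
    hospitals: pd.DataFrame,
    S: np.ndarray,
    P: np.ndarray,
    travel: TravelTimeMatrix,
    decay: DecaySpec,
    method: str,
    variant: str = "decay_consistent",
) -> AccessibilityIndex:
    """Accessibility index AI per cell and per-hospital partial indices.

    The AI of cell x sums, over reachable hospitals y, the hospital's
    attractiveness weighted by decay (squared for M2SFCA) and divided by
    the hospital's decay-weighted demand ``D_y = sum_x P_x f(d_xy)``.
    """
    if method not in ("m2sfca", "e2sfca"):
        raise ValueError(f"compute_ai supports m2sfca/e2sfca, got {method!r}")
    if variant not in ("as_printed", "decay_consistent"):
        raise ValueError(f"unknown variant {variant!r}")
    cell_ids = cells["cell_id"].to_numpy()
    hospital_ids = hospitals["hospital_id"].to_numpy()
    S = np.asarray(S, dtype=float)
    P = np.asarray(P, dtype=float)
    minutes, reachable = travel.dense(cell_ids, hospital_ids)
    F = _decay_matrix(minutes, reachable, decay)

    D = P @ F  # decay-weighted demand per hospital
    has_cells = reachable.any(axis=0)
    isolated = has_cells & (D <= 0) & (S > 0)
    if isolated.any():
        raise IsolatedHospitalError(
            f"zero demand denominator for hospitals {list(hospital_ids[isolated])}"
        )
    safe_D = np.where(D > 0, D, 1.0)
    active = D > 0

    if method == "m2sfca":
        summand = (S[np.newaxis, :] * F * F) / safe_D[np.newaxis, :]
        printed_partial = (S[np.newaxis, :] * F) / safe_D[np.newaxis, :]
    else:  # e2sfca
        summand = (S[np.newaxis, :] * F) / safe_D[np.newaxis, :]
        # printed partial has no decay term: constant per hospital on reachable pairs
        printed_partial = reachable * (S / safe_D)[np.newaxis, :]
    summand[:, ~active] = 0.0
    printed_partial[:, ~active] = 0.0

    ai = summand.sum(axis=1)
    partials = summand if variant == "decay_consistent" else printed_partial
    return AccessibilityIndex(
        ai=ai,
        partials=partials,
        cell_ids=cell_ids,
        hospital_ids=hospital_ids,
        method=method,
        variant=variant,
    )


def weights_from_partials(ai: AccessibilityIndex) -> WeightMatrix:
    """Visit weights W(x,y) = partial AI(x,y) / AI(x); zero where AI is zero."""
    positive = ai.ai > 0
    W = np.divide(
        ai.partials,
        ai.ai[:, np.newaxis],
        out=np.zeros_like(ai.partials),
        where=positive[:, np.newaxis],
    )
    return WeightMatrix(
        weights=W, cell_ids=ai.cell_ids, hospital_ids=ai.hospital_ids, method=ai.method
    )


def predict_visits(W: WeightMatrix, P: np.ndarray, diagnosis: str = "") -> PredictionResult:
    """Eq.-1 aggregation: V_y = sum_x W(x,y) P_x (unfactorized)."""
    P = np.asarray(P, dtype=float)
    V = W.weights.T @ P
    return PredictionResult(
        method=W.method,
        diagnosis=diagnosis,
        visits=pd.Series(V, index=W.hospital_ids),
        factorized=False,
    )


def closest_provider_predict(
    cells: pd.DataFrame,
    hospitals: pd.DataFrame,
    travel: TravelTimeMatrix,
    P: np.ndarray,
    diagnosis: str = "",
) -> PredictionResult:
    """Benchmark: all of each cell's need goes to its nearest reachable hospital.

    Ties are broken deterministically toward the lowest hospital id; cells
    with no hospital inside the catchment are logged and contribute no
    visits.
    """
    order = np.argsort(hospitals["hospital_id"].to_numpy(), kind="stable")
    hospitals = hospitals.iloc[order]
    cell_ids = cells["cell_id"].to_numpy()
    hospital_ids = hospitals["hospital_id"].to_numpy()
    minutes, reachable = travel.dense(cell_ids, hospital_ids)
    P = np.asarray(P, dtype=float)
    V = np.zeros(len(hospital_ids))
    any_reachable = reachable.any(axis=1)
    if (~any_reachable).any():
        unreached = cell_ids[~any_reachable]
        logger.info(
            "closest-provider: %d unreachable cells with total need %.3f skipped: %s",
            len(unreached),
            float(P[~any_reachable].sum()),
            list(unreached[:10]),
        )
    # argmin over columns sorted by hospital_id returns the lowest id on ties
    nearest = np.argmin(minutes, axis=1)
    for i in np.nonzero(any_reachable)[0]:
        V[nearest[i]] += P[i]
    return PredictionResult(
        method="closest",
        diagnosis=diagnosis,
        visits=pd.Series(V, index=hospital_ids),
        factorized=False,
    )


def factorize(pred: PredictionResult, actual: pd.Series) -> PredictionResult:
    """Rescale predictions so their total equals the actual total.

    Exclusion rules make the predicted and actual totals differ; a single
    multiplicative factor ``sum(actual) / sum(predicted)`` restores the
    total while preserving the spatial pattern.
    """
    total_pred = float(pred.visits.sum())
    if total_pred <= 0:
        raise FactorizationError("cannot factorize: predicted total is zero")
    total_actual = float(actual.reindex(pred.visits.index).sum())
    scale = total_actual / total_pred
    return PredictionResult(
        method=pred.method,
        diagnosis=pred.diagnosis,
        visits=pred.visits * scale,
        factorized=True,
        scale_factor=scale,
        attractiveness_source=pred.attractiveness_source,
    )


def _specialty_for(scenario: Scenario, diagnosis: str, config: PipelineConfig) -> str:
    if diagnosis in config.specialty_of:
        return config.specialty_of[diagnosis]
    specialties = scenario.specialties
    if len(specialties) == 1:
        return specialties[0]
    raise KeyError(
        f"no specialty configured for diagnosis {diagnosis!r} and the scenario has several"
    )


def run_method(
    scenario: Scenario,
    diagnosis: str,
    method: str,
    attractiveness_source: str = "beds",
    config: PipelineConfig | None = None,
) -> PredictionResult:
    """End-to-end prediction for one method and diagnosis.

    Applies, in order: hospital exclusion (specialty capacity and minimum
    diagnosis counts), method-specific weights, the visit aggregation, and
    factorization against the actual visits of the included hospitals.
    ``attractiveness_source`` selects beds (operational) or actual visits
    (the hypothetical best-case attractiveness).
    """
    config = config or PipelineConfig()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    specialty = _specialty_for(scenario, diagnosis, config)
    marked = exclude_hospitals(scenario.hospitals, diagnosis, specialty, config.min_counts)
    excluded = marked[~marked["included"]]
    if len(excluded):
        logger.info(
            "%s/%s: excluded %d hospitals: %s",
            method,
            diagnosis,
            len(excluded),
            list(excluded["hospital_id"][:10]),
        )
    hospitals = marked[marked["included"]].reset_index(drop=True)
    if hospitals.empty:
        raise ValueError(f"no hospitals remain after exclusion for {diagnosis!r}")
    actual = pd.Series(
        hospitals[visits_column(diagnosis)].to_numpy(dtype=float),
        index=hospitals["hospital_id"].to_numpy(),
    )
    if attractiveness_source == "beds":
        S = hospitals[beds_column(specialty)].to_numpy(dtype=float)
    elif attractiveness_source == "actual_visits":
        S = actual.to_numpy()
    else:
        raise ValueError(f"unknown attractiveness source {attractiveness_source!r}")
    P = scenario.need(diagnosis).to_numpy()

    if method == "closest":
        pred = closest_provider_predict(scenario.cells, hospitals, scenario.travel, P, diagnosis)
    elif method == "ifca":
        W = ifca_weights(scenario.cells, hospitals, S, scenario.travel, config.decay_for("ifca"))
        pred = predict_visits(W, P, diagnosis)
    else:
        ai = compute_ai(
            scenario.cells,
            hospitals,
            S,
            P,
            scenario.travel,
            config.decay_for(method),
            method,
            config.variant,
        )
        pred = predict_visits(weights_from_partials(ai), P, diagnosis)
    pred.attractiveness_source = attractiveness_source
    return factorize(pred, actual)
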