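"""Accuracy protocol for predicted versus actual hospital visits.

Per method and diagnosis: Spearman rank correlation (average ranks for
ties, asymptotic two-sided p), ordinary least squares of actual on
predicted with R² and residual diagnostics, the proportion of hospitals
predicted within ±5/10/15% of their actual visits, extreme signed
deviations, and a Kruskal–Wallis comparison across methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpearmanResult",
    "RegressionResult",
    "EvaluationReport",
    "spearman",
    "regression_r2",
    "band_accuracy",
    "kruskal_wallis",
    "deviation_summary",
    "evaluate",
]

DEFAULT_BANDS = (0.05, 0.10, 0.15)


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    undefined: bool  # True when a vector is constant and the correlation is undefined


def _vectors(pred, actual) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("pred and actual must have equal length")
    return pred, actual


def spearman(pred, actual) -> SpearmanResult:
    """Spearman's rho with average ranks for ties and asymptotic two-sided p."""
    pred, actual = _vectors(pred, actual)
    if len(pred) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(pred) == 0 or np.ptp(actual) == 0:
        return SpearmanResult(np.nan, np.nan, True)
    res = stats.spearmanr(pred, actual)
    return SpearmanResult(float(res.statistic), float(res.pvalue), False)


@dataclass
class RegressionResult:
    """OLS of actual (dependent) on predicted (independent)."""

    r_squared: float
    slope: float
    intercept: float
    p_value: float
    fitted: np.ndarray
    residuals: np.ndarray
    std_residuals: np.ndarray  # data for the residual-normality histogram

    def residual_frame(self) -> pd.DataFrame:
        """Data for the homoscedasticity (residuals-vs-fitted) plot."""
        return pd.DataFrame(
            {
                "fitted": self.fitted,
                "residual": self.residuals,
                "std_residual": self.std_residuals,
            }
        )


def regression_r2(pred, actual) -> RegressionResult:
    """Least-squares fit actual ~ predicted with R² and residual diagnostics."""
    pred, actual = _vectors(pred, actual)
    if len(pred) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(pred) == 0:
        raise ValueError("degenerate fit: predictor has zero variance")
    fit = stats.linregress(pred, actual)
    fitted = fit.intercept + fit.slope * pred
    resid = actual - fitted
    sd = resid.std(ddof=2)
    std_resid = resid / sd if sd > 0 else np.zeros_like(resid)
    # a constant response has no variance to explain: the null fit, R^2 = 0
    r2 = float(fit.rvalue**2) if np.ptp(actual) > 0 else 0.0
    return RegressionResult(
        r_squared=r2,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        fitted=fitted,
        residuals=resid,
        std_residuals=std_resid,
    )


def band_accuracy(pred, actual, band: float) -> float:
    """Proportion of hospitals with |pred - actual| <= band * actual.

    The boundary is inclusive.  Hospitals with zero actual visits have no
    defined relative error and are excluded from the denominator (use
    :func:`evaluate` to get their count).
    """
    pred, actual = _vectors(pred, actual)
    mask = actual > 0
    if not mask.any():
        return np.nan
    ok = np.abs(pred[mask] - actual[mask]) <= band * actual[mask]
    return float(ok.mean())


def kruskal_wallis(predictions: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) across per-method visit vectors.

    Identical values across all groups give (H, p) = (0, 1).
    """
    groups = [np.asarray(v, dtype=float) for v in predictions.values()]
    if len(groups) < 2:
        raise ValueError("need at least two methods to compare")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def deviation_summary(pred, actual, ids=None) -> dict:
    """Extreme signed deviations pred - actual (as positive magnitudes).

    Returns max positive and max negative deviation with the hospital id
    at which each occurs; a direction with no deviation reports 0.
    """
    pred, actual = _vectors(pred, actual)
    if ids is None:
        ids = np.arange(len(pred))
    ids = np.asarray(ids)
    dev = pred - actual
    max_pos = float(max(dev.max(), 0.0))
    max_neg = float(max(-dev.min(), 0.0))
    return {
        "max_positive_deviation": max_pos,
        "max_positive_hospital": ids[int(np.argmax(dev))] if max_pos > 0 else None,
        "max_negative_deviation": max_neg,
        "max_negative_hospital": ids[int(np.argmin(dev))] if max_neg > 0 else None,
    }


@dataclass
class EvaluationReport:
    """Accuracy summary for one method × diagnosis prediction."""

    method: str
    diagnosis: str
    attractiveness_source: str
    n_hospitals: int
    n_zero_actual: int
    spearman_rho: float
    spearman_p: float
    r_squared: float
    regression_p: float
    slope: float
    intercept: float
    band_accuracy: dict = field(default_factory=dict)  # band fraction -> proportion
    max_positive_deviation: float = 0.0
    max_negative_deviation: float = 0.0

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "diagnosis": self.diagnosis,
            "attractiveness": self.attractiveness_source,
            "n_hospitals": self.n_hospitals,
            "n_zero_actual": self.n_zero_actual,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "r_squared": self.r_squared,
            "regression_p": self.regression_p,
            "slope": self.slope,
            "intercept": self.intercept,
            "max_positive_deviation": self.max_positive_deviation,
            "max_negative_deviation": self.max_negative_deviation,
        }
        for band, prop in self.band_accuracy.items():
            out[f"band_{int(round(band * 100))}pct"] = prop
        return out


def evaluate(
    pred,
    actual,
    method: str = "",
    diagnosis: str = "",
    attractiveness_source: str = "beds",
    bands: Sequence[float] = DEFAULT_BANDS,
) -> EvaluationReport:
    """Assemble the full accuracy report for one prediction.

    Band proportions are checked for nestedness (a wider band can never
    contain fewer hospitals) on every call.
    """
    pred, actual = _vectors(pred, actual)
    rho = spearman(pred, actual)
    reg = regression_r2(pred, actual)
    bands = tuple(sorted(bands))
    band_props = {b: band_accuracy(pred, actual, b) for b in bands}
    props = [band_props[b] for b in bands]
    if any(b2 < b1 - 1e-12 for b1, b2 in zip(props, props[1:])):
        raise AssertionError("band accuracy must be non-decreasing in band width")
    dev = deviation_summary(pred, actual)
    return EvaluationReport(
        method=method,
        diagnosis=diagnosis,
        attractiveness_source=attractiveness_source,
        n_hospitals=int(len(pred)),
        n_zero_actual=int((actual == 0).sum()),
        spearman_rho=rho.rho,
        spearman_p=rho.p,
        r_squared=reg.r_squared,
        regression_p=reg.p_value,
        slope=reg.slope,
        intercept=reg.intercept,
        band_accuracy=band_props,
        max_positive_deviation=dev["max_positive_deviation"],
        max_negative_deviation=dev["max_negative_deviation"],
    )
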