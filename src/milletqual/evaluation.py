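"""Model-performance statistics: MRD, RMSE, NRMSE and the four-category
classification used in agronomic model evaluation.

MRD (mean relative difference, %) measures bias; RMSE the typical error in
the variable's units; NRMSE (RMSE over the observation mean, %) a
scale-free error binned as excellent (< 10%), good (10–20%), moderate
(20–30%) or poor (>= 30%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .crop_state import QualitySeries
from .synthetic import ObservationSet

logger = logging.getLogger(__name__)

__all__ = ["EvalResult", "mrd", "rmse", "nrmse", "classify_nrmse", "evaluate"]


@dataclass(frozen=True)
class EvalResult:
    """Evaluation of one variable: pair count, MRD (%), RMSE (variable
    units), NRMSE (%) and the NRMSE performance category."""

    n: int
    mrd: float
    rmse: float
    nrmse: float
    category: str

    def to_dict(self, variable: str | None = None) -> dict:
        out = {"n": self.n, "mrd_pct": self.mrd, "rmse": self.rmse,
               "nrmse_pct": self.nrmse, "category": self.category}
        if variable is not None:
            out = {"variable": variable, **out}
        return out


def _paired(pred, obs) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.size == 0:
        raise ValueError("need at least one prediction/observation pair")
    return pred, obs


def mrd(pred, obs) -> float:
    """Mean relative difference, percent: mean((P - O)/O) x 100.

    Pairs with a zero observation are undefined under this formula and are
    excluded with a logged warning.
    """
    pred, obs = _paired(pred, obs)
    usable = obs != 0
    if not np.all(usable):
        logger.warning("mrd: excluding %d pair(s) with zero observations",
                       int(np.sum(~usable)))
    if not np.any(usable):
        raise ValueError("no usable pairs: all observations are zero")
    return float(np.mean((pred[usable] - obs[usable]) / obs[usable]) * 100.0)


def rmse(pred, obs) -> float:
    """Root mean square error in the variable's units."""
    pred, obs = _paired(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def nrmse(pred, obs) -> float:
    """Normalized RMSE, percent of the observation mean."""
    pred, obs = _paired(pred, obs)
    o_avg = float(np.mean(obs))
    if o_avg == 0:
        raise ValueError("observation mean is zero; NRMSE undefined")
    return rmse(pred, obs) / o_avg * 100.0


def classify_nrmse(value: float) -> str:
    """Performance category for an NRMSE percentage.

    Half-open bins: excellent < 10 <= good < 20 <= moderate < 30 <= poor.
    """
    if value < 0:
        raise ValueError(f"NRMSE must be >= 0, got {value}")
    if value < 10:
        return "excellent"
    if value < 20:
        return "good"
    if value < 30:
        return "moderate"
    return "poor"


def evaluate(qs: QualitySeries, obs: ObservationSet) -> EvalResult:
    """Evaluate a simulated quality series against sparse observations.

    Predictions are paired to observations by exact ``day_index`` match (no
    interpolation); a sampled day missing from the series is an error.
    """
    column = obs.variable.lower()
    if column not in qs.frame.columns:
        raise ValueError(f"quality series has no column for {obs.variable!r}")
    by_day = qs.frame.set_index("day_index")[column]
    days = obs.days()
    missing = [int(d) for d in days if d not in by_day.index]
    if missing:
        raise ValueError(f"observation days {missing} absent from the series")
    pred = by_day.loc[days].to_numpy(dtype=float)
    ovals = obs.values()
    score = nrmse(pred, ovals)
    return EvalResult(n=len(days), mrd=mrd(pred, ovals),
                      rmse=rmse(pred, ovals), nrmse=score,
                      category=classify_nrmse(score))
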