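"""Daily water- and nitrogen-stress factors shared by the protein and starch
modules.

Both factors are dimensionless indices in [0, 1] where 1 means no stress:
water stress is the ratio of actual to potential transpiration, nitrogen
stress a linear ramp of the plant nitrogen concentration between its minimum
and critical values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StressPair", "water_stress", "nitrogen_stress"]


@dataclass(frozen=True)
class StressPair:
    """Water (``fw``) and nitrogen (``fn``) stress factors, each in [0, 1]."""

    fw: float
    fn: float


def water_stress(ta, tp):
    """Water-stress factor f(W) = Ta/Tp clamped to [0, 1].

    Zero potential transpiration means no evaporative demand, hence no
    stress (factor 1).  Accepts scalars or arrays.
    """
    ta = np.asarray(ta, dtype=float)
    tp = np.asarray(tp, dtype=float)
    if np.any(ta < 0) or np.any(tp < 0):
        raise ValueError("transpiration must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        fw = np.where(tp > 0, ta / np.where(tp > 0, tp, 1.0), 1.0)
    fw = np.clip(fw, 0.0, 1.0)
    return float(fw) if fw.ndim == 0 else fw


def nitrogen_stress(anp, cnp, mnp):
    """Nitrogen-stress factor f(N) = min(1, (ANP - MNP)/(CNP - MNP)).

    The ramp is additionally clamped below at 0 so downstream enzyme-activity
    products stay in [0, 1].  Accepts scalars or arrays.
    """
    anp = np.asarray(anp, dtype=float)
    cnp = np.asarray(cnp, dtype=float)
    mnp = np.asarray(mnp, dtype=float)
    if np.any(cnp <= mnp):
        raise ValueError("critical N concentration must exceed the minimum")
    fn = np.clip((anp - mnp) / (cnp - mnp), 0.0, 1.0)
    return float(fn) if fn.ndim == 0 else fn
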