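"""Grain-protein module: stress-modulated nitrogen-to-protein conversion.

Grain protein accumulation is grain nitrogen accumulation times a
nitrogen-to-protein conversion factor (NPF).  The NPF rises from a baseline
``npf0`` by up to ``delta`` as the more limiting of the water and nitrogen
stress factors relaxes toward 1:

    NPF_i = delta * min(f(W_i), f(N_i)) + npf0

so with the calibrated defaults (npf0 = 5.83, delta = 0.18) NPF lies in
[5.83, 6.01], fully unstressed days giving the 6.01 endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crop_state import CropStateSeries
from .stress import nitrogen_stress, water_stress

__all__ = ["ProteinParams", "npf", "protein_accumulation"]


@dataclass(frozen=True)
class ProteinParams:
    """Calibrated grain-protein-module parameters.

    ``npf0``: baseline nitrogen-to-protein conversion factor (dimensionless).
    ``delta``: stress-dependent correction added on top of the baseline.
    """

    npf0: float = 5.83
    delta: float = 0.18

    def __post_init__(self):
        if self.npf0 <= 0:
            raise ValueError(f"npf0 must be > 0, got {self.npf0}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")


def npf(fw, fn, params: ProteinParams = ProteinParams()):
    """Nitrogen-to-protein conversion factor from the day's stress pair.

    Bounded in [npf0, npf0 + delta]; scalar or array inputs.
    """
    fw = np.asarray(fw, dtype=float)
    fn = np.asarray(fn, dtype=float)
    if np.any((fw < 0) | (fw > 1)) or np.any((fn < 0) | (fn > 1)):
        raise ValueError("stress factors must lie in [0, 1]")
    out = params.delta * np.minimum(fw, fn) + params.npf0
    return float(out) if out.ndim == 0 else out


def protein_accumulation(
    series: CropStateSeries, params: ProteinParams = ProteinParams()
) -> pd.DataFrame:
    """Daily grain protein accumulation (kg/ha) along the series.

    Each day's NPF uses that day's stress factors (no smoothing or lag);
    the anthesis day is evaluated too so cumulative plots start at day 0.
    Returns a frame with columns ``day_index, fw, fn, npf, gpa``.
    """
    fw = water_stress(series.col("ta"), series.col("tp"))
    fn = nitrogen_stress(series.col("anp"), series.col("cnp"), series.col("mnp"))
    conv = npf(fw, fn, params)
    gpa = series.col("gna") * conv
    return pd.DataFrame({
        "day_index": series.frame["day_index"].to_numpy(),
        "fw": fw, "fn": fn, "npf": conv, "gpa": gpa,
    })
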