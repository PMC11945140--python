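"""Grain-starch module: carbon supply, enzyme-activity limitation,
Michaelis–Menten synthesis and the amylose/amylopectin partition.

The daily chain is:

1. Carbon supply.  Before the remobilization onset (accumulated thermal time
   below ``gdd_m``) grains receive only the immediate photosynthate
   GCP = ΔTOPWT − ΔVWT; afterwards they receive all new aboveground growth
   (GCP = ΔTOPWT) plus the dry matter remobilized from vegetative organs
   (GCT = −ΔVWT).  The canopy flux is converted to a per-grain substrate
   GCA = 1e6 (GCP + GCT)/(SP·Ng), mg per grain.
2. Enzyme activity.  Starch-synthase activity is the product of a lifecycle
   factor of thermal time (exponential rise to a peak at ``gdd_m``, linear
   decline to zero at maturity), a cardinal-temperature response, and the
   water and nitrogen stress factors.
3. Synthesis.  The per-grain rate follows Michaelis–Menten kinetics,
   ISTR = ISTRm · Eact · GCA/(Km + GCA), integrated daily into the per-grain
   starch amount IGSA and scaled by grain number to the canopy total GSA.
4. Partition.  The amylose fraction RA = (α ln GDD − β)·f(N), clamped to
   [0, 1], splits GSA into amylose (GASA) and amylopectin (GAPA).

Defaults are the calibrated values for foxtail millet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crop_state import CropStateSeries, QualitySeries
from .protein import ProteinParams, npf
from .stress import nitrogen_stress, water_stress

__all__ = [
    "StarchParams", "PartitionParams", "carbon_supply", "lifecycle_factor",
    "temperature_factor", "enzyme_activity", "starch_rate", "amylose_ratio",
    "simulate_starch",
]


@dataclass(frozen=True)
class StarchParams:
    """Grain-starch-module parameters (calibrated defaults for millet).

    Parameters
    ----------
    igsa0 : float
        Initial starch content per grain at anthesis, mg.
    istr_m : float
        Maximum per-grain starch accumulation rate, mg/day.
    km : float
        Michaelis constant — the substrate level (mg/grain) at which the
        synthesis rate is half its maximum.
    gdd_m : float
        Thermal time from anthesis to peak amylase activity, °C d; also the
        onset of assimilate remobilization.
    gamma : float
        Sensitivity of amylase activity to thermal time, 1/(°C d).
    tb, tol, toh, tm : float
        Cardinal temperatures (min, optimal-low, optimal-high, max) for
        starch formation, °C.
    cap_rate_to_supply : bool
        If true, additionally cap the daily rate at the day's substrate
        supply (mass balance); off by default, which is the literal
        Michaelis–Menten form.
    """

    igsa0: float = 0.1
    istr_m: float = 1.2
    km: float = 0.7
    gdd_m: float = 256.0
    gamma: float = 0.002
    tb: float = 7.0
    tol: float = 22.0
    toh: float = 27.0
    tm: float = 60.0
    cap_rate_to_supply: bool = False

    def __post_init__(self):
        if self.igsa0 < 0:
            raise ValueError(f"igsa0 must be >= 0, got {self.igsa0}")
        for name in ("istr_m", "km", "gdd_m", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (self.tb < self.tol <= self.toh < self.tm):
            raise ValueError(
                "cardinal temperatures must satisfy tb < tol <= toh < tm, got "
                f"{self.tb}, {self.tol}, {self.toh}, {self.tm}")


@dataclass(frozen=True)
class PartitionParams:
    """Amylose/amylopectin partition parameters.

    ``alpha`` scales the natural log of thermal time; ``beta`` is the
    baseline correction.  The resulting amylose ratio is treated as a
    fraction in [0, 1].
    """

    alpha: float = 0.4
    beta: float = 2.1

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")


def carbon_supply(
    series: CropStateSeries, gdd_m: float, debug: bool = False
) -> pd.DataFrame:
    """Daily carbon supply to grains: GCP, GCT (kg/ha) and GCA (mg/grain).

    Day 0 supplies nothing.  Increments that come out negative (senescing
    canopy pre-onset, vegetative regrowth post-onset) are floored at zero so
    the Michaelis–Menten substrate stays nonnegative; with ``debug=True``
    the unfloored values are kept in ``gcp_raw``/``gct_raw`` columns.
    """
    if series.sp * series.ng == 0:
        raise ValueError("sp * ng must be positive to convert to per-grain units")
    topwt = series.col("topwt")
    vwt = series.col("vwt")
    gdd = series.col("gdd")
    n = len(topwt)

    gcp_raw = np.zeros(n)
    gct_raw = np.zeros(n)
    dtop = np.diff(topwt)
    dvwt = np.diff(vwt)
    post = gdd[1:] >= gdd_m
    gcp_raw[1:] = np.where(post, dtop, dtop - dvwt)
    gct_raw[1:] = np.where(post, -dvwt, 0.0)

    gcp = np.maximum(0.0, gcp_raw)
    gct = np.maximum(0.0, gct_raw)
    gca = 1e6 * (gcp + gct) / (series.sp * series.ng)
    out = {"day_index": series.frame["day_index"].to_numpy(),
           "gcp": gcp, "gct": gct, "gca": gca}
    if debug:
        out["gcp_raw"] = gcp_raw
        out["gct_raw"] = gct_raw
    return pd.DataFrame(out)


def lifecycle_factor(gdd, gdd_m: float, gamma: float, gdd_am: float):
    """Lifecycle effect on amylase activity, in [0, 1].

    Exponential rise to 1 at ``gdd_m`` — (GDD/GDDm)·exp[γ(GDDm − GDD)] —
    then a linear decline to 0 at ``gdd_am``.  Clamped to [0, 1]; with the
    calibrated parameters (γ·GDDm ≈ 0.51) the clamp is inert.
    """
    if gdd_m >= gdd_am:
        raise ValueError(f"gdd_m ({gdd_m}) must be below gdd_am ({gdd_am})")
    gdd = np.asarray(gdd, dtype=float)
    rising = (gdd / gdd_m) * np.exp(gamma * (gdd_m - gdd))
    falling = (gdd_am - gdd) / (gdd_am - gdd_m)
    f = np.where(gdd <= gdd_m, rising, falling)
    f = np.clip(f, 0.0, 1.0)
    return float(f) if f.ndim == 0 else f


def temperature_factor(t, params: StarchParams = StarchParams()):
    """Cardinal-temperature response of starch formation, in [0, 1].

    Sine ramp from ``tb`` up to the optimal plateau [``tol``, ``toh``),
    sine ramp down to ``tm``, zero outside [``tb``, ``tm``]; continuous at
    all four breakpoints.
    """
    t = np.asarray(t, dtype=float)
    tb, tol, toh, tm = params.tb, params.tol, params.toh, params.tm
    f = np.zeros_like(t)
    up = (t >= tb) & (t < tol)
    f = np.where(up, np.sin((t - tb) / (tol - tb) * np.pi / 2), f)
    f = np.where((t >= tol) & (t < toh), 1.0, f)
    down = (t >= toh) & (t <= tm)
    f = np.where(down, np.sin((tm - t) / (tm - toh) * np.pi / 2), f)
    f = np.clip(f, 0.0, 1.0)
    return float(f) if f.ndim == 0 else f


def enzyme_activity(f_gdd, f_t, fw, fn):
    """Combined enzyme-activity limiting factor: the product of the four
    component factors, each required to lie in [0, 1]."""
    arrs = [np.asarray(a, dtype=float) for a in (f_gdd, f_t, fw, fn)]
    for name, a in zip(("f_gdd", "f_t", "fw", "fn"), arrs):
        if np.any((a < 0) | (a > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    eact = arrs[0] * arrs[1] * arrs[2] * arrs[3]
    return float(eact) if eact.ndim == 0 else eact


def starch_rate(gca, eact, istr_m: float = 1.2, km: float = 0.7,
                cap_rate_to_supply: bool = False):
    """Per-grain starch synthesis rate, mg/day (Michaelis–Menten).

    ``istr = istr_m * eact * gca / (km + gca)``; at ``gca = km`` and full
    enzyme activity the rate is half its maximum.  The optional cap bounds
    the rate by the day's substrate supply.
    """
    gca = np.asarray(gca, dtype=float)
    eact = np.asarray(eact, dtype=float)
    if np.any(gca < 0):
        raise ValueError("gca must be nonnegative")
    istr = istr_m * eact * gca / (km + gca)
    if cap_rate_to_supply:
        istr = np.minimum(istr, gca)
    return float(istr) if istr.ndim == 0 else istr


def amylose_ratio(gdd, fn, pparams: PartitionParams = PartitionParams()):
    """Amylose fraction of total starch, clamped to [0, 1].

    ``ra = (alpha * ln(gdd) - beta) * fn``; zero at gdd = 0 (no thermal
    time accumulated yet).
    """
    gdd = np.asarray(gdd, dtype=float)
    fn = np.asarray(fn, dtype=float)
    if np.any(gdd < 0):
        raise ValueError("gdd must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(gdd > 0,
                       (pparams.alpha * np.log(np.where(gdd > 0, gdd, 1.0))
                        - pparams.beta) * fn,
                       0.0)
    ra = np.clip(raw, 0.0, 1.0)
    return float(ra) if ra.ndim == 0 else ra


def simulate_starch(
    series: CropStateSeries,
    sparams: StarchParams = StarchParams(),
    pparams: PartitionParams = PartitionParams(),
    protein_params: ProteinParams = ProteinParams(),
) -> QualitySeries:
    """Run the full daily grain-quality simulation over a crop-state series.

    Integrates the per-grain starch pool from anthesis to maturity
    (``igsa[i] = igsa[i-1] + istr[i]``, starting from ``igsa0``), scales to
    the canopy total, partitions amylose/amylopectin, and fills the protein
    columns so the result carries every diagnostic of the quality-series
    CSV.
    """
    if sparams.gdd_m >= series.gdd_am:
        raise ValueError(
            f"gdd_m ({sparams.gdd_m}) must be below the series gdd_am "
            f"({series.gdd_am})")

    gdd = series.col("gdd")
    fw = water_stress(series.col("ta"), series.col("tp"))
    fn = nitrogen_stress(series.col("anp"), series.col("cnp"),
                         series.col("mnp"))
    conv = npf(fw, fn, protein_params)
    gpa = series.col("gna") * conv

    supply = carbon_supply(series, sparams.gdd_m)
    f_gdd = lifecycle_factor(gdd, sparams.gdd_m, sparams.gamma, series.gdd_am)
    f_t = temperature_factor(series.col("tavg"), sparams)
    eact = enzyme_activity(f_gdd, f_t, fw, fn)
    gca = supply["gca"].to_numpy()
    istr = starch_rate(gca, eact, sparams.istr_m, sparams.km,
                       sparams.cap_rate_to_supply)
    istr[0] = 0.0  # anthesis day carries the initial pool only

    igsa = sparams.igsa0 + np.cumsum(istr)
    gsa = series.sp * series.ng * igsa * 1e-6
    ra = amylose_ratio(gdd, fn, pparams)
    gasa = gsa * ra
    gapa = gsa * (1.0 - ra)

    frame = pd.DataFrame({
        "day_index": series.frame["day_index"].to_numpy(),
        "gdd": gdd, "fw": fw, "fn": fn, "npf": conv, "gpa": gpa,
        "gcp": supply["gcp"].to_numpy(), "gct": supply["gct"].to_numpy(),
        "gca": gca, "f_gdd": f_gdd, "f_t": f_t, "eact": eact,
        "istr": istr, "igsa": igsa, "gsa": gsa, "ra": ra,
        "gasa": gasa, "gapa": gapa,
    })
    return QualitySeries(frame=frame, sp=series.sp, ng=series.ng)
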