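"""Seeded synthetic crop-state trajectories and sparse noisy observations.

The generator emulates the post-anthesis daily outputs of a process-based
cereal growth model: sigmoid aboveground biomass, a vegetative pool that
tracks the canopy until the remobilization onset and then declines as dry
matter is transferred to grains, logistic grain-nitrogen accumulation,
declining critical/minimum nitrogen dilution curves, and configurable
drought / nitrogen-deficit episodes expressed through the transpiration
ratio and a depressed plant nitrogen concentration.  It exists so that every
downstream stage — simulation, calibration, evaluation — is testable without
a full crop-model run or field data.

All randomness flows through one generator seeded per call; identical
configurations produce byte-identical series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crop_state import (
    DEFAULT_GDD_BASE, CropStateSeries, QualitySeries, compute_gdd,
)

__all__ = ["ScenarioConfig", "StressWindow", "ObservationSet",
           "generate_scenario", "make_observations"]


@dataclass(frozen=True)
class StressWindow:
    """A stress episode: days ``start``..``end`` (inclusive) with the given
    transpiration ratio (water stress) and plant-N depression fraction
    (nitrogen stress; 0 = none, 1 = down to the minimum concentration)."""

    start: int
    end: int
    ta_tp_ratio: float = 1.0
    n_depression: float = 0.0


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic post-anthesis scenario.

    Defaults sketch a rain-fed foxtail millet stand: ~45 days from anthesis
    to maturity, aboveground biomass rising from 6 to 12 t/ha along a
    logistic, a quarter of the vegetative dry weight remobilized to grains
    after the onset, grain N accumulating logistically to 100 kg/ha, and a
    mild grain-filling season (21 ± 2 °C, so ~11 °C d accumulate per day
    above the 10 °C base and the season totals ~500 °C d).  The default
    remobilization onset (day 21) is where that thermal time crosses the
    calibrated amylase-activity peak of 256 °C d.
    """

    duration: int = 45
    topwt_at_anthesis: float = 6000.0
    topwt_final: float = 12000.0
    growth_midpoint: float = 20.0
    growth_rate: float = 0.25
    remobilization_onset: int = 21
    remobilization_fraction: float = 0.25
    gna_final: float = 100.0
    gna_rate: float = 0.22
    gna_midpoint: float = 22.0
    temp_mean: float = 21.0
    temp_amplitude: float = 2.0
    temp_noise_sd: float = 0.5
    stress_windows: list[StressWindow] = field(default_factory=list)
    sp: float = 3.5e5
    ng: float = 5000.0
    cnp0: float = 0.025
    mnp0: float = 0.010
    gdd_base: float = DEFAULT_GDD_BASE
    seed: int = 0
    scenario_meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.duration < 3:
            raise ValueError(f"duration must be >= 3, got {self.duration}")
        for name in ("topwt_at_anthesis", "topwt_final", "gna_final",
                     "sp", "ng"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.remobilization_fraction <= 1:
            raise ValueError("remobilization_fraction must lie in [0, 1]")
        if not 0 < self.remobilization_onset < self.duration:
            raise ValueError("remobilization_onset must lie inside the season")
        if not self.cnp0 > self.mnp0 > 0:
            raise ValueError("need cnp0 > mnp0 > 0")
        for w in self.stress_windows:
            if not 0 <= w.start <= w.end <= self.duration:
                raise ValueError(f"stress window {w} outside [0, duration]")
            if not (0 <= w.ta_tp_ratio <= 1 and 0 <= w.n_depression <= 1):
                raise ValueError(f"stress window ratios must lie in [0, 1]: {w}")


@dataclass
class ObservationSet:
    """Sparse sampled values of one quality variable for calibration or
    evaluation; mirrors destructive spike sampling every 7–10 days from
    anthesis to maturity."""

    variable: str
    samples: pd.DataFrame  # columns: day_index, value, sd

    def days(self) -> np.ndarray:
        return self.samples["day_index"].to_numpy(dtype=int)

    def values(self) -> np.ndarray:
        return self.samples["value"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, variable: str) -> "ObservationSet":
        return cls(variable=variable, samples=pd.read_csv(path))


def _bounded_logistic(day: np.ndarray, lo: float, hi: float,
                      midpoint: float, rate: float) -> np.ndarray:
    """Logistic rescaled to hit ``lo`` exactly at day 0 and ``hi`` on the
    final day, preserving monotonicity and (approximate) midpoint symmetry."""
    s = 1.0 / (1.0 + np.exp(-rate * (day - midpoint)))
    s0 = 1.0 / (1.0 + np.exp(rate * midpoint))
    s1 = 1.0 / (1.0 + np.exp(-rate * (day[-1] - midpoint)))
    return lo + (hi - lo) * (s - s0) / (s1 - s0)


def generate_scenario(cfg: ScenarioConfig) -> CropStateSeries:
    """Generate one seeded daily crop-state series from anthesis to maturity.

    The vegetative pool equals the canopy until the remobilization onset,
    then releases ``remobilization_fraction`` of its onset value along a
    smoothstep, so the grain-mass proxy (topwt − vwt) never shrinks.
    Stress-free configurations produce f(W) = f(N) = 1 on every day.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    day = np.arange(cfg.duration + 1, dtype=float)
    n = day.size

    topwt = _bounded_logistic(day, cfg.topwt_at_anthesis, cfg.topwt_final,
                              cfg.growth_midpoint, cfg.growth_rate)
    vwt = topwt.copy()
    onset = cfg.remobilization_onset
    u = np.clip((day - onset) / (cfg.duration - onset), 0.0, 1.0)
    ramp = u * u * (3.0 - 2.0 * u)  # smoothstep 0 -> 1
    vwt = np.where(day >= onset,
                   vwt[onset] - cfg.remobilization_fraction * vwt[onset] * ramp,
                   vwt)

    gna = _bounded_logistic(day, 0.0, cfg.gna_final,
                            cfg.gna_midpoint, cfg.gna_rate)

    tavg = (cfg.temp_mean
            + cfg.temp_amplitude * np.sin(np.pi * day / cfg.duration))
    if cfg.temp_noise_sd > 0:
        tavg = tavg + rng.normal(0.0, cfg.temp_noise_sd, size=n)

    # nitrogen dilution: critical/minimum curves decline gently with age
    dilution = 1.0 - 0.3 * day / cfg.duration
    cnp = cfg.cnp0 * dilution
    mnp = cfg.mnp0 * dilution

    tp = np.full(n, 4.0)
    ta = tp.copy()
    depression = np.zeros(n)
    for w in cfg.stress_windows:
        mask = (day >= w.start) & (day <= w.end)
        ta[mask] = np.minimum(ta[mask], w.ta_tp_ratio * tp[mask])
        depression[mask] = np.maximum(depression[mask], w.n_depression)
    anp = cnp - depression * (cnp - mnp)

    frame = pd.DataFrame({
        "day_index": np.arange(cfg.duration + 1),
        "tavg": tavg, "topwt": topwt, "vwt": vwt, "gna": gna,
        "ta": ta, "tp": tp, "anp": anp, "cnp": cnp, "mnp": mnp,
    })
    frame["gdd"] = compute_gdd(tavg, cfg.gdd_base)
    return CropStateSeries(
        frame=frame, sp=cfg.sp, ng=cfg.ng,
        gdd_am=float(frame["gdd"].iloc[-1]),
        scenario_meta=dict(cfg.scenario_meta),
    )


#: Observation variables resolvable from a quality series (upper-case name
#: -> CSV column).
_QS_VARIABLES = {"GPA": "gpa", "GSA": "gsa", "GASA": "gasa", "GAPA": "gapa"}


def make_observations(
    qs: QualitySeries,
    variable: str,
    sampling_interval: int = 7,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> ObservationSet:
    """Sample a simulated quality variable every ``sampling_interval`` days
    (plus the final day) with multiplicative Gaussian noise of coefficient
    of variation ``noise_cv``, floored at zero.  ``noise_cv = 0`` returns
    the truth exactly."""
    if len(qs) == 0:
        raise ValueError("empty quality series")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    key = variable.upper()
    if key not in _QS_VARIABLES:
        raise ValueError(
            f"unknown observation variable {variable!r}; "
            f"choose one of {sorted(_QS_VARIABLES)}")
    col = _QS_VARIABLES[key]

    n = len(qs)
    days = np.arange(0, n, sampling_interval)
    if days[-1] != n - 1:
        days = np.append(days, n - 1)
    truth = qs.col(col)[days]

    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        values = np.maximum(0.0, truth * (1.0 + rng.normal(0, noise_cv,
                                                           size=truth.size)))
    else:
        values = truth.copy()
    samples = pd.DataFrame({
        "day_index": qs.frame["day_index"].to_numpy()[days],
        "value": values,
        "sd": noise_cv * truth,
    })
    return ObservationSet(variable=key, samples=samples)


def stressed_scenario(seed: int = 0) -> ScenarioConfig:
    """A convenience scenario with mid-season drought and late nitrogen
    deficit, used for calibration fixtures where stress variation is needed
    to identify the stress-sensitive parameters."""
    return ScenarioConfig(
        stress_windows=[
            StressWindow(start=10, end=20, ta_tp_ratio=0.75, n_depression=0.2),
            StressWindow(start=30, end=40, ta_tp_ratio=0.9, n_depression=0.45),
        ],
        seed=seed,
    )
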