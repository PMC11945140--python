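"""Shared fixtures: synthetic scenarios and an independent quality oracle.

The oracle recomputes the whole daily chain (stress factors, carbon supply,
enzyme activity, Michaelis–Menten rate, integration, partition) with plain
per-day Python loops and scalar math, deliberately sharing no array code
with the package's vectorized simulator, so agreement between the two is a
meaningful cross-check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from milletqual import (PartitionParams, ProteinParams, ScenarioConfig,
                        StarchParams, generate_scenario)
from milletqual.synthetic import StressWindow, stressed_scenario


@pytest.fixture
def default_series():
    return generate_scenario(ScenarioConfig(seed=7))


@pytest.fixture
def quiet_series():
    """Stress-free, noise-free scenario."""
    return generate_scenario(ScenarioConfig(temp_noise_sd=0.0, seed=3))


@pytest.fixture
def stressed_series():
    return generate_scenario(stressed_scenario(seed=11))


def random_scenario(seed: int) -> ScenarioConfig:
    """A randomized but valid scenario for property-style sweeps."""
    rng = np.random.default_rng(seed)
    duration = int(rng.integers(30, 61))
    onset = int(rng.integers(10, duration - 5))
    windows = []
    if rng.random() < 0.6:
        start = int(rng.integers(0, duration - 5))
        end = int(rng.integers(start, duration))
        windows.append(StressWindow(
            start=start, end=end,
            ta_tp_ratio=float(rng.uniform(0.4, 1.0)),
            n_depression=float(rng.uniform(0.0, 0.8))))
    return ScenarioConfig(
        duration=duration,
        topwt_at_anthesis=float(rng.uniform(4000, 8000)),
        topwt_final=float(rng.uniform(9000, 14000)),
        growth_midpoint=float(rng.uniform(10, duration - 10)),
        growth_rate=float(rng.uniform(0.15, 0.35)),
        remobilization_onset=onset,
        remobilization_fraction=float(rng.uniform(0.1, 0.4)),
        gna_final=float(rng.uniform(60, 140)),
        temp_mean=float(rng.uniform(18, 26)),
        temp_amplitude=float(rng.uniform(0, 4)),
        temp_noise_sd=float(rng.uniform(0, 1.5)),
        stress_windows=windows,
        sp=float(rng.uniform(2e5, 5e5)),
        ng=float(rng.uniform(2000, 8000)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def oracle_quality(series, sparams: StarchParams = StarchParams(),
                   pparams: PartitionParams = PartitionParams(),
                   prparams: ProteinParams = ProteinParams()) -> pd.DataFrame:
    """Independent single-pass scalar recomputation of the daily chain."""
    rows = []
    days = list(series)
    igsa_prev = sparams.igsa0
    for i, d in enumerate(days):
        fw = 1.0 if d.tp == 0 else min(1.0, max(0.0, d.ta / d.tp))
        fn = min(1.0, max(0.0, (d.anp - d.mnp) / (d.cnp - d.mnp)))
        conv = prparams.delta * min(fw, fn) + prparams.npf0
        gpa = d.gna * conv

        if i == 0:
            gcp = gct = gca = istr = 0.0
        else:
            prev = days[i - 1]
            if d.gdd < sparams.gdd_m:
                gcp = (d.topwt - prev.topwt) - (d.vwt - prev.vwt)
                gct = 0.0
            else:
                gcp = d.topwt - prev.topwt
                gct = prev.vwt - d.vwt
            gcp = max(0.0, gcp)
            gct = max(0.0, gct)
            gca = 1e6 * (gcp + gct) / (series.sp * series.ng)

        if d.gdd <= sparams.gdd_m:
            f_gdd = (d.gdd / sparams.gdd_m) * math.exp(
                sparams.gamma * (sparams.gdd_m - d.gdd))
        else:
            f_gdd = (series.gdd_am - d.gdd) / (series.gdd_am - sparams.gdd_m)
        f_gdd = min(1.0, max(0.0, f_gdd))

        t = d.tavg
        if t < sparams.tb or t > sparams.tm:
            f_t = 0.0
        elif t < sparams.tol:
            f_t = math.sin((t - sparams.tb) / (sparams.tol - sparams.tb)
                           * math.pi / 2)
        elif t < sparams.toh:
            f_t = 1.0
        else:
            f_t = math.sin((sparams.tm - t) / (sparams.tm - sparams.toh)
                           * math.pi / 2)
        f_t = min(1.0, max(0.0, f_t))

        eact = f_gdd * f_t * fw * fn
        if i > 0:
            istr = sparams.istr_m * eact * gca / (sparams.km + gca)
            if sparams.cap_rate_to_supply:
                istr = min(istr, gca)

        igsa = igsa_prev + istr
        igsa_prev = igsa
        gsa = series.sp * series.ng * igsa * 1e-6

        if d.gdd == 0:
            ra = 0.0
        else:
            ra = min(1.0, max(0.0, (pparams.alpha * math.log(d.gdd)
                                    - pparams.beta) * fn))
        rows.append({
            "day_index": d.day_index, "gdd": d.gdd, "fw": fw, "fn": fn,
            "npf": conv, "gpa": gpa, "gcp": gcp, "gct": gct, "gca": gca,
            "f_gdd": f_gdd, "f_t": f_t, "eact": eact, "istr": istr,
            "igsa": igsa, "gsa": gsa, "ra": ra, "gasa": gsa * ra,
            "gapa": gsa * (1 - ra),
        })
    return pd.DataFrame(rows)
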