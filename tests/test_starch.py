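"""Grain-starch module: carbon supply, enzyme activity, Michaelis–Menten
kinetics, daily integration and the amylose/amylopectin partition."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import oracle_quality, random_scenario
from milletqual import (CropStateSeries, PartitionParams, StarchParams,
                        amylose_ratio, carbon_supply, compute_gdd,
                        enzyme_activity, generate_scenario, lifecycle_factor,
                        simulate_starch, starch_rate, temperature_factor)


def _two_day_series(topwt, vwt, gdd, sp=4e5, ng=2000):
    frame = pd.DataFrame({
        "day_index": [0, 1], "tavg": 22.0, "topwt": topwt, "vwt": vwt,
        "gna": 0.0, "ta": 4.0, "tp": 4.0,
        "anp": 0.02, "cnp": 0.02, "mnp": 0.01, "gdd": gdd,
    })
    return CropStateSeries(frame=frame, sp=sp, ng=ng, gdd_am=gdd[-1])


class TestCarbonSupply:
    def test_pre_onset_day_subtracts_vegetative_growth(self):
        s = _two_day_series([6000.0, 6150.0], [5000.0, 5100.0],
                            [0.0, 100.0])
        out = carbon_supply(s, gdd_m=256.0)
        assert out["gcp"].iloc[1] == pytest.approx(50.0)
        assert out["gct"].iloc[1] == pytest.approx(0.0)

    def test_post_onset_day_adds_remobilized_matter(self):
        s = _two_day_series([6000.0, 6120.0], [5000.0, 4970.0],
                            [300.0, 310.0])
        out = carbon_supply(s, gdd_m=256.0)
        assert out["gcp"].iloc[1] == pytest.approx(120.0)
        assert out["gct"].iloc[1] == pytest.approx(30.0)

    def test_per_grain_conversion(self):
        s = _two_day_series([6000.0, 6080.0], [5000.0, 5000.0],
                            [300.0, 310.0], sp=4e5, ng=2000)
        out = carbon_supply(s, gdd_m=256.0)
        # 80 kg/ha over 8e8 grains -> 0.1 mg per grain
        assert out["gca"].iloc[1] == pytest.approx(0.1)

    def test_negative_increments_floored_but_kept_in_debug(self):
        s = _two_day_series([6000.0, 5950.0], [5000.0, 5020.0],
                            [300.0, 310.0])
        out = carbon_supply(s, gdd_m=256.0, debug=True)
        assert out["gcp"].iloc[1] == 0.0 and out["gct"].iloc[1] == 0.0
        assert out["gcp_raw"].iloc[1] == pytest.approx(-50.0)
        assert out["gct_raw"].iloc[1] == pytest.approx(-20.0)

    def test_zero_grain_number_rejected(self):
        s = _two_day_series([6000.0, 6100.0], [5000.0, 5000.0],
                            [0.0, 10.0])
        s.ng = 0.0
        with pytest.raises(ValueError):
            carbon_supply(s, gdd_m=256.0)


class TestLifecycleFactor:
    def test_peak_is_one_from_both_branches(self):
        assert lifecycle_factor(256.0, 256.0, 0.002, 500.0) == \
            pytest.approx(1.0, abs=1e-12)
        assert lifecycle_factor(256.0 + 1e-9, 256.0, 0.002, 500.0) == \
            pytest.approx(1.0, abs=1e-6)

    def test_rising_branch_value(self):
        assert lifecycle_factor(128.0, 256.0, 0.002, 500.0) == \
            pytest.approx(0.5 * math.exp(0.256), rel=1e-12)

    def test_zero_at_maturity(self):
        assert lifecycle_factor(500.0, 256.0, 0.002, 500.0) == 0.0

    def test_onset_at_or_beyond_maturity_rejected(self):
        with pytest.raises(ValueError):
            lifecycle_factor(100.0, 500.0, 0.002, 500.0)

    def test_clamp_inert_with_calibrated_parameters(self):
        # gamma * gdd_m = 0.512 < 1, so the exponential branch peaks below 1
        grid = np.linspace(0.0, 500.0, 5001)
        vals = lifecycle_factor(grid, 256.0, 0.002, 500.0)
        raw = np.where(grid <= 256.0,
                       grid / 256.0 * np.exp(0.002 * (256.0 - grid)),
                       (500.0 - grid) / (500.0 - 256.0))
        np.testing.assert_allclose(vals, raw, atol=1e-12)


class TestTemperatureFactor:
    @pytest.mark.parametrize("t, expected", [
        (25.0, 1.0),                       # inside the optimal plateau
        (14.5, math.sin(math.pi / 4)),     # midpoint of the ascending ramp
        (5.0, 0.0),                        # below the minimum temperature
        (65.0, 0.0),                       # above the maximum temperature
        (43.5, math.sin(math.pi / 4)),     # midpoint of the descending ramp
    ])
    def test_cardinal_response(self, t, expected):
        assert temperature_factor(t) == pytest.approx(expected, abs=1e-12)

    def test_continuous_at_all_breakpoints(self):
        eps = 1e-9
        for bp in (7.0, 22.0, 27.0, 60.0):
            left = temperature_factor(bp - eps)
            right = temperature_factor(bp + eps)
            at = temperature_factor(bp)
            assert abs(left - at) < 1e-6 and abs(right - at) < 1e-6

    def test_invalid_cardinal_ordering_rejected(self):
        with pytest.raises(ValueError):
            StarchParams(tb=25.0, tol=22.0)


class TestEnzymeActivity:
    def test_product_of_factors(self):
        assert enzyme_activity(1.0, 1.0, 0.8, 0.5) == pytest.approx(0.4)
        assert enzyme_activity(1.0, 1.0, 1.0, 1.0) == 1.0
        assert enzyme_activity(0.0, 1.0, 0.9, 0.9) == 0.0

    def test_out_of_range_factor_rejected(self):
        with pytest.raises(ValueError):
            enzyme_activity(1.1, 1.0, 1.0, 1.0)


class TestStarchRate:
    def test_half_saturation(self):
        assert starch_rate(0.7, 1.0, istr_m=1.2, km=0.7) == \
            pytest.approx(0.6, abs=1e-15)

    def test_no_substrate_no_synthesis(self):
        assert starch_rate(0.0, 1.0) == 0.0

    def test_saturates_below_maximum(self):
        big = starch_rate(0.7e6, 1.0, istr_m=1.2, km=0.7)
        assert big < 1.2 and big == pytest.approx(1.2, rel=1e-5)

    def test_supply_cap(self):
        # at tiny substrate the uncapped rate exceeds the supply itself
        gca = 0.01
        assert starch_rate(gca, 1.0) > gca
        assert starch_rate(gca, 1.0, cap_rate_to_supply=True) == gca

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            starch_rate(-0.1, 1.0)


class TestAmyloseRatio:
    def test_direct_evaluation(self):
        assert amylose_ratio(500.0, 1.0) == \
            pytest.approx(0.4 * math.log(500.0) - 2.1, rel=1e-12)

    def test_negative_raw_value_clamped(self):
        assert amylose_ratio(100.0, 1.0) == 0.0

    def test_nitrogen_annihilation_and_zero_thermal_time(self):
        assert amylose_ratio(500.0, 0.0) == 0.0
        assert amylose_ratio(0.0, 1.0) == 0.0


class TestSimulateStarch:
    def test_frozen_kinetics_when_enzyme_activity_is_zero(self,
                                                          default_series):
        s = default_series
        s.frame["anp"] = s.frame["mnp"] * 0.5  # fn = 0 everywhere
        qs = simulate_starch(s)
        np.testing.assert_allclose(qs.col("igsa"), 0.1, atol=1e-12)
        np.testing.assert_allclose(qs.col("gsa"),
                                   s.sp * s.ng * 0.1e-6, atol=1e-12)

    def test_canopy_scaling_arithmetic(self, default_series):
        qs = simulate_starch(default_series)
        np.testing.assert_allclose(
            qs.col("gsa"),
            default_series.sp * default_series.ng * qs.col("igsa") * 1e-6,
            rtol=1e-12)

    def test_onset_beyond_maturity_rejected(self, default_series):
        with pytest.raises(ValueError):
            simulate_starch(default_series,
                            StarchParams(gdd_m=default_series.gdd_am + 1))

    def test_conservation_and_telescoping(self, default_series):
        qs = simulate_starch(default_series)
        np.testing.assert_allclose(qs.col("gasa") + qs.col("gapa"),
                                   qs.col("gsa"), atol=1e-9)
        assert qs.final("igsa") == pytest.approx(
            0.1 + qs.col("istr").sum(), abs=1e-9)
        assert np.all(np.diff(qs.col("gsa")) >= -1e-12)

    def test_unit_round_trip_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sp, ng = rng.uniform(1e4, 1e6), rng.uniform(100, 10000)
            flux = rng.uniform(0, 500)           # kg/ha
            per_grain = 1e6 * flux / (sp * ng)   # mg/grain
            back = sp * ng * per_grain * 1e-6    # kg/ha
            assert back == pytest.approx(flux, rel=1e-12)

    def test_matches_independent_oracle(self, stressed_series):
        qs = simulate_starch(stressed_series)
        ref = oracle_quality(stressed_series)
        for col in qs.frame.columns:
            np.testing.assert_allclose(qs.col(col), ref[col].to_numpy(),
                                       atol=1e-9, err_msg=col)

    def test_final_gsa_monotone_in_any_days_substrate(self, quiet_series):
        qs = simulate_starch(quiet_series)
        gca = qs.col("gca")
        eact = qs.col("eact")
        base_final = qs.final("igsa")
        for day in (5, 22, 30, 44):
            bumped = gca.copy()
            bumped[day] *= 1.5
            istr = starch_rate(bumped, eact)
            istr[0] = 0.0
            assert 0.1 + istr.sum() >= base_final - 1e-12
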