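"""Crop-state containers, CSV I/O and thermal-time accumulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milletqual import (compute_gdd, read_crop_state_csv, read_quality_csv,
                        simulate_starch, validate_series, write_quality_csv)
from milletqual.crop_state import (CROP_STATE_COLUMNS, QUALITY_COLUMNS,
                                   FormatError, ParseError, ValidationError)


def _frame(n=3, tavg=(22.0, 20.0, 25.0), with_gdd=False):
    f = pd.DataFrame({
        "day_index": range(n),
        "tavg": tavg[:n],
        "topwt": np.linspace(6000, 6400, n),
        "vwt": np.linspace(5900, 5800, n),
        "gna": np.linspace(0, 10, n),
        "ta": 4.0, "tp": 4.0,
        "anp": 0.02, "cnp": 0.02, "mnp": 0.01,
    })
    if with_gdd:
        f["gdd"] = compute_gdd(f["tavg"].to_numpy())
    return f


class TestComputeGdd:
    @pytest.mark.parametrize("tavg, base, expected", [
        ([22.0, 20.0, 25.0], 10.0, [0.0, 10.0, 25.0]),
        ([22.0, 5.0], 10.0, [0.0, 0.0]),        # sub-base day contributes 0
        ([10.0, 10.0, 10.0], 10.0, [0.0, 0.0, 0.0]),
    ])
    def test_hand_summation(self, tavg, base, expected):
        np.testing.assert_allclose(compute_gdd(np.array(tavg), base), expected)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            compute_gdd(np.array([]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 45), min_size=1, max_size=60),
           st.floats(0, 15))
    def test_matches_incremental_loop_and_is_nondecreasing(self, tavg, base):
        got = compute_gdd(np.array(tavg), base)
        acc, expect = 0.0, [0.0]
        for t in tavg[1:]:
            acc += max(0.0, t - base)
            expect.append(acc)
        np.testing.assert_allclose(got, expect, atol=1e-12)
        assert np.all(np.diff(got) >= 0)


class TestReadCropStateCsv:
    def test_direct_ingestion(self, tmp_path):
        path = tmp_path / "cs.csv"
        _frame(n=2, with_gdd=True).to_csv(path, index=False)
        series = read_crop_state_csv(path, sp=3e5, ng=4000)
        assert len(series) == 2
        assert series.gdd_am == series.frame["gdd"].iloc[-1]

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "cs.csv"
        _frame().drop(columns=["vwt"]).to_csv(path, index=False)
        with pytest.raises(FormatError, match="vwt"):
            read_crop_state_csv(path, sp=3e5, ng=4000)

    def test_gdd_computed_when_absent(self, tmp_path):
        path = tmp_path / "cs.csv"
        _frame(n=3, tavg=(18.0, 20.0, 25.0)).to_csv(path, index=False)
        series = read_crop_state_csv(path, sp=3e5, ng=4000, gdd_base=10.0)
        np.testing.assert_allclose(series.col("gdd"), [0.0, 10.0, 25.0])

    def test_non_numeric_cell_reports_row_and_column(self, tmp_path):
        path = tmp_path / "cs.csv"
        f = _frame().astype(object)
        f.loc[1, "topwt"] = "oops"
        f.to_csv(path, index=False)
        with pytest.raises(ParseError, match=r"row 1.*topwt"):
            read_crop_state_csv(path, sp=3e5, ng=4000)

    def test_invariant_violations_raise_with_all_issues(self, tmp_path):
        path = tmp_path / "cs.csv"
        f = _frame(with_gdd=True)
        f.loc[1, "vwt"] = f.loc[1, "topwt"] + 1  # vwt > topwt
        f.loc[2, "gna"] = -5.0
        f.to_csv(path, index=False)
        with pytest.raises(ValidationError) as err:
            read_crop_state_csv(path, sp=3e5, ng=4000)
        fields = {f for _, f, _ in err.value.report.issues}
        assert {"vwt", "gna"} <= fields


class TestValidateSeries:
    def test_well_formed_series_passes(self, default_series):
        report = validate_series(default_series)
        assert report.ok and report.issues == []

    def test_vwt_above_topwt_flagged_with_day(self, default_series):
        default_series.frame.loc[5, "vwt"] = \
            default_series.frame.loc[5, "topwt"] + 1
        report = validate_series(default_series)
        assert not report.ok
        assert (5, "vwt") in {(r, f) for r, f, _ in report.issues}

    def test_non_consecutive_days_flagged(self, default_series):
        default_series.frame.loc[3, "day_index"] = 99
        report = validate_series(default_series)
        assert not report.ok
        assert any(f == "day_index" for _, f, _ in report.issues)


class TestQualityCsv:
    def test_round_trip_within_1e9(self, tmp_path, default_series):
        qs = simulate_starch(default_series)
        path = tmp_path / "quality.csv"
        write_quality_csv(qs, path)
        back = read_quality_csv(path)
        for col in QUALITY_COLUMNS:
            np.testing.assert_allclose(back.col(col), qs.col(col), atol=1e-9)

    def test_header_order_is_canonical(self, tmp_path, default_series):
        path = tmp_path / "quality.csv"
        write_quality_csv(simulate_starch(default_series), path)
        header = path.read_text().splitlines()[0].split(",")
        assert header == QUALITY_COLUMNS

    def test_empty_series_rejected(self, tmp_path, default_series):
        qs = simulate_starch(default_series)
        qs.frame = qs.frame.iloc[0:0]
        with pytest.raises(ValueError):
            write_quality_csv(qs, tmp_path / "q.csv")


def test_crop_state_csv_round_trip(tmp_path, default_series):
    from milletqual import write_crop_state_csv
    path = tmp_path / "cs.csv"
    write_crop_state_csv(default_series, path)
    back = read_crop_state_csv(path, sp=default_series.sp,
                               ng=default_series.ng)
    for col in CROP_STATE_COLUMNS + ["gdd"]:
        np.testing.assert_allclose(back.col(col), default_series.col(col),
                                   atol=1e-9)
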