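"""Daily crop-state containers, canonical CSV I/O and thermal-time accumulation.

The simulator consumes one row per day from anthesis (day 0) to physiological
maturity: biomass pools, grain nitrogen, transpiration and plant nitrogen
status as a process-based crop model (or the synthetic generator) would emit
them.  All grain-quality equations index days after anthesis, so day 0 carries
the anthesis-time state used as the previous-day baseline for day 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mandatory columns of the canonical crop-state CSV (``gdd`` is optional and
#: recomputed from ``tavg`` when absent).
CROP_STATE_COLUMNS = [
    "day_index", "tavg", "topwt", "vwt", "gna",
    "ta", "tp", "anp", "cnp", "mnp",
]

#: Canonical column order of the quality-series CSV.
QUALITY_COLUMNS = [
    "day_index", "gdd", "fw", "fn", "npf", "gpa", "gcp", "gct", "gca",
    "f_gdd", "f_t", "eact", "istr", "igsa", "gsa", "ra", "gasa", "gapa",
]

#: Default base temperature for thermal-time accumulation, °C.
DEFAULT_GDD_BASE = 10.0


class CropStateError(ValueError):
    """Base class for crop-state input problems."""


class FormatError(CropStateError):
    """A mandatory column is missing from the input file."""


class ParseError(CropStateError):
    """A cell could not be interpreted as a number."""


class ValidationError(CropStateError):
    """One or more series invariants are violated."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = "; ".join(f"row {r}, {f}: {m}" for r, f, m in report.issues)
        super().__init__(f"crop-state series failed validation: {lines}")


@dataclass(frozen=True)
class DailyCropState:
    """Crop state on one day after anthesis.

    Parameters
    ----------
    day_index : int
        Days after anthesis; 0 is the anthesis day itself.
    tavg : float
        Daily mean air temperature, °C.
    topwt : float
        Aboveground dry weight, kg/ha.
    vwt : float
        Vegetative-organ dry weight, kg/ha.
    gna : float
        Grain nitrogen accumulation, kg/ha.
    ta, tp : float
        Actual and potential transpiration, mm/day.
    anp, cnp, mnp : float
        Actual, critical and minimum plant nitrogen concentration (mass
        fraction); the critical/minimum pair defines the nitrogen-stress
        ramp.
    gdd : float
        Accumulated thermal time since anthesis, °C d.
    """

    day_index: int
    tavg: float
    topwt: float
    vwt: float
    gna: float
    ta: float
    tp: float
    anp: float
    cnp: float
    mnp: float
    gdd: float


@dataclass
class CropStateSeries:
    """Daily crop states from anthesis to maturity plus scenario scalars.

    ``sp`` (spikes/ha) and ``ng`` (grains/spike) are scenario constants used
    to convert canopy fluxes (kg/ha) to per-grain amounts (mg) and back;
    ``gdd_am`` is the accumulated thermal time from anthesis to maturity.
    """

    frame: pd.DataFrame
    sp: float
    ng: float
    gdd_am: float
    scenario_meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[DailyCropState]:
        for row in self.frame.itertuples(index=False):
            yield DailyCropState(
                day_index=int(row.day_index), tavg=row.tavg, topwt=row.topwt,
                vwt=row.vwt, gna=row.gna, ta=row.ta, tp=row.tp, anp=row.anp,
                cnp=row.cnp, mnp=row.mnp, gdd=row.gdd,
            )

    def col(self, name: str) -> np.ndarray:
        """Column as a float array."""
        return self.frame[name].to_numpy(dtype=float)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_series`: ``ok`` iff ``issues`` is empty."""

    ok: bool
    issues: list[tuple[int, str, str]]


@dataclass
class QualitySeries:
    """Daily simulated grain-quality outputs (one row per day).

    Columns follow :data:`QUALITY_COLUMNS`: stress factors (``fw``, ``fn``),
    nitrogen-to-protein conversion (``npf``) and protein accumulation
    (``gpa``, kg/ha); carbon supply to grains (``gcp``, ``gct`` in kg/ha,
    ``gca`` in mg/grain); enzyme-activity factors (``f_gdd``, ``f_t``,
    ``eact``); per-grain starch rate and amount (``istr`` mg/day, ``igsa``
    mg); canopy starch (``gsa``, kg/ha); and the amylose fraction ``ra``
    with the amylose/amylopectin split (``gasa``, ``gapa``, kg/ha).
    """

    frame: pd.DataFrame
    sp: float | None = None
    ng: float | None = None

    def __len__(self) -> int:
        return len(self.frame)

    def col(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    def final(self, name: str) -> float:
        return float(self.frame[name].iloc[-1])


def compute_gdd(tavg: np.ndarray, gdd_base: float = DEFAULT_GDD_BASE) -> np.ndarray:
    """Accumulated thermal time since anthesis, °C d.

    Day 0 (anthesis) contributes nothing; each later day adds
    ``max(0, tavg - gdd_base)``, so the series is nondecreasing.
    """
    tavg = np.asarray(tavg, dtype=float)
    if tavg.size == 0:
        raise ValueError("empty temperature series")
    if gdd_base < 0:
        raise ValueError(f"gdd_base must be >= 0, got {gdd_base}")
    inc = np.maximum(0.0, tavg - gdd_base)
    inc[0] = 0.0
    return np.cumsum(inc)


def validate_series(series: CropStateSeries) -> ValidationReport:
    """Check every series invariant row-wise and collect all violations."""
    issues: list[tuple[int, str, str]] = []
    f = series.frame
    day = f["day_index"].to_numpy()
    n = len(f)

    expected = np.arange(n)
    if not np.array_equal(day, expected):
        bad = int(np.argmax(day != expected)) if n else 0
        issues.append((bad, "day_index",
                       "day_index values must be consecutive starting at 0"))

    for i in range(n):
        row = f.iloc[i]
        if not (row["topwt"] >= row["vwt"] >= 0):
            issues.append((i, "vwt", f"need topwt >= vwt >= 0, got "
                           f"topwt={row['topwt']}, vwt={row['vwt']}"))
        if row["gna"] < 0:
            issues.append((i, "gna", f"gna must be >= 0, got {row['gna']}"))
        if row["ta"] < 0:
            issues.append((i, "ta", f"ta must be >= 0, got {row['ta']}"))
        if row["tp"] < 0:
            issues.append((i, "tp", f"tp must be >= 0, got {row['tp']}"))
        if not (row["cnp"] > row["mnp"]):
            issues.append((i, "cnp", f"need cnp > mnp, got cnp={row['cnp']}, "
                           f"mnp={row['mnp']}"))
        if row["gdd"] < 0:
            issues.append((i, "gdd", f"gdd must be >= 0, got {row['gdd']}"))

    gdd = f["gdd"].to_numpy(dtype=float)
    if n > 1 and np.any(np.diff(gdd) < 0):
        bad = int(np.argmax(np.diff(gdd) < 0)) + 1
        issues.append((bad, "gdd", "gdd must be nondecreasing"))
    if n and abs(gdd[-1] - series.gdd_am) > 1e-6:
        issues.append((n - 1, "gdd",
                       f"last-day gdd {gdd[-1]} != gdd_am {series.gdd_am}"))
    if not series.sp > 0:
        issues.append((0, "sp", f"sp must be > 0, got {series.sp}"))
    if not series.ng > 0:
        issues.append((0, "ng", f"ng must be > 0, got {series.ng}"))

    return ValidationReport(ok=not issues, issues=issues)


def read_crop_state_csv(
    path: str | Path,
    sp: float,
    ng: float,
    gdd_base: float = DEFAULT_GDD_BASE,
) -> CropStateSeries:
    """Read the canonical crop-state CSV into a validated series.

    The ``gdd`` column is recomputed via :func:`compute_gdd` when absent;
    ``gdd_am`` is taken from the last row.  Raises :class:`FormatError` on a
    missing column, :class:`ParseError` on a non-numeric cell and
    :class:`ValidationError` (listing every issue) on violated invariants.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    for colname in CROP_STATE_COLUMNS:
        if colname not in frame.columns:
            raise FormatError(f"missing mandatory column '{colname}' in {path}")

    keep = list(CROP_STATE_COLUMNS) + (["gdd"] if "gdd" in frame.columns else [])
    frame = frame[keep]
    for colname in keep:
        try:
            frame[colname] = pd.to_numeric(frame[colname])
        except (ValueError, TypeError):
            coerced = pd.to_numeric(frame[colname], errors="coerce")
            row = int(coerced.index[coerced.isna()][0])
            raise ParseError(
                f"non-numeric value {frame[colname].iloc[row]!r} at row {row}, "
                f"column '{colname}' in {path}"
            ) from None

    frame = frame.sort_values("day_index").reset_index(drop=True)
    if "gdd" not in frame.columns:
        frame["gdd"] = compute_gdd(frame["tavg"].to_numpy(dtype=float), gdd_base)

    series = CropStateSeries(
        frame=frame, sp=sp, ng=ng, gdd_am=float(frame["gdd"].iloc[-1]),
        scenario_meta={"source": str(path)},
    )
    report = validate_series(series)
    if not report.ok:
        raise ValidationError(report)
    return series


def write_crop_state_csv(series: CropStateSeries, path: str | Path) -> None:
    """Write a series to the canonical crop-state CSV (with ``gdd``)."""
    cols = CROP_STATE_COLUMNS + ["gdd"]
    series.frame[cols].to_csv(path, index=False)


def write_quality_csv(qs: QualitySeries, path: str | Path) -> None:
    """Write a quality series in the canonical column order.

    Full repr precision is kept so that re-reading reproduces every value
    to better than 1e-9.
    """
    if len(qs) == 0:
        raise ValueError("cannot write an empty quality series")
    qs.frame[QUALITY_COLUMNS].to_csv(path, index=False)


def read_quality_csv(path: str | Path) -> QualitySeries:
    """Read a quality-series CSV written by :func:`write_quality_csv`."""
    frame = pd.read_csv(path)
    missing = [c for c in QUALITY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing quality columns {missing} in {path}")
    return QualitySeries(frame=frame[QUALITY_COLUMNS])
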