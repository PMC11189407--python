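"""Input tables, conception-date estimation and model-frame assembly.

Two delimited text tables drive the analysis:

* a birth table with columns ``year, month, boys, girls`` (one row per birth
  month, aggregated counts), and
* a temperature table with columns ``year, month, temp_c`` (mean monthly air
  temperature, °C), also accepted in year x 12-month wide layout.

The conception date of a birth month is estimated as the 15th of that month
minus 280 days of gestation (true calendar arithmetic, leap-aware); lag ``k``
then refers to the calendar month ``k`` months after (``k > 0``) or before
(``k < 0``) the conception month.  The model frame holds one row per birth
month with the response ``(girls, total)`` and all temperature covariates.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

log = logging.getLogger("ssrlag")

GESTATION_DAYS = 280
ASSUMED_BIRTH_DAY = 15
LAGS = range(-9, 10)


class TableFormatError(ValueError):
    """A delimited input table violates the schema."""


class CoverageError(ValueError):
    """Temperature coverage is insufficient for a requested computation."""


class ConceptionEstimate(NamedTuple):
    birth_year: int
    birth_month: int
    conception_date: dt.date
    conception_year: int
    conception_month: int


# ------------------------------------------------------------------ readers

def _read_delimited(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_birth_table(path) -> pd.DataFrame:
    """Read and validate a birth table, returned sorted by (year, month).

    Accepts the deposited dataset's column spellings through a thin alias map
    (``males/boys``, ``females/girls``).
    """
    df = _read_delimited(path)
    alias = {"males": "boys", "male": "boys", "females": "girls", "female": "girls",
             "n_boys": "boys", "n_girls": "girls"}
    df = df.rename(columns=alias)
    required = ["year", "month", "boys", "girls"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    df = df[required].astype(int)
    return validate_birth_series(df, origin=str(path))


def validate_birth_series(df: pd.DataFrame, origin: str = "<birth table>") -> pd.DataFrame:
    bad = df[(df["month"] < 1) | (df["month"] > 12)]
    if len(bad):
        raise TableFormatError(f"{origin}: month outside 1..12 in row(s) {bad.index.tolist()[:5]}")
    neg = df[(df["boys"] < 0) | (df["girls"] < 0)]
    if len(neg):
        raise TableFormatError(f"{origin}: negative counts in row(s) {neg.index.tolist()[:5]}")
    dup = df.duplicated(subset=["year", "month"])
    if dup.any():
        raise TableFormatError(f"{origin}: duplicate (year, month) in row(s) {df.index[dup].tolist()[:5]}")
    return df.sort_values(["year", "month"], ignore_index=True)


def read_temperature_table(path) -> pd.DataFrame:
    """Read a temperature table in long (year, month, temp_c) or wide layout."""
    df = _read_delimited(path)
    if "temp_c" not in df.columns and "temp" in df.columns:
        df = df.rename(columns={"temp": "temp_c"})
    if {"year", "month", "temp_c"}.issubset(df.columns):
        out = df[["year", "month", "temp_c"]].copy()
    elif "year" in df.columns and df.shape[1] >= 13:
        month_cols = [c for c in df.columns if c != "year"][:12]
        long = df.melt(id_vars="year", value_vars=month_cols,
                       var_name="month", value_name="temp_c")
        name_map = {m.lower(): i + 1 for i, m in enumerate(
            ["jan", "feb", "mar", "apr", "may", "jun", "jul", "aug", "sep", "oct", "nov", "dec"])}
        long["month"] = [name_map.get(str(m).strip().lower()[:3], m) for m in long["month"]]
        out = long
    else:
        raise TableFormatError(f"{path}: expected (year, month, temp_c) or year x 12-month layout")
    out["year"] = out["year"].astype(int)
    out["month"] = out["month"].astype(int)
    out["temp_c"] = out["temp_c"].astype(float)
    return validate_temperature_series(out, origin=str(path))


def validate_temperature_series(df: pd.DataFrame, origin: str = "<temperature table>") -> pd.DataFrame:
    if ((df["month"] < 1) | (df["month"] > 12)).any():
        raise TableFormatError(f"{origin}: month outside 1..12")
    if not np.isfinite(df["temp_c"]).all():
        raise TableFormatError(f"{origin}: non-finite temperature values")
    if df.duplicated(subset=["year", "month"]).any():
        raise TableFormatError(f"{origin}: duplicate (year, month)")
    return df.sort_values(["year", "month"], ignore_index=True)


def write_birth_table(df: pd.DataFrame, path) -> None:
    df[["year", "month", "boys", "girls"]].to_csv(path, index=False)


def write_temperature_table(df: pd.DataFrame, path) -> None:
    df[["year", "month", "temp_c"]].to_csv(path, index=False)


# ---------------------------------------------------------------- conception

def estimate_conception(birth_year: int, birth_month: int) -> ConceptionEstimate:
    """Conception date = 15th of the birth month minus 280 days of gestation."""
    if not 1 <= birth_month <= 12:
        raise ValueError(f"birth month must be 1..12, got {birth_month}")
    cdate = dt.date(birth_year, birth_month, ASSUMED_BIRTH_DAY) - dt.timedelta(days=GESTATION_DAYS)
    return ConceptionEstimate(birth_year, birth_month, cdate, cdate.year, cdate.month)


def shift_month(year: int, month: int, k: int) -> tuple[int, int]:
    """The calendar month ``k`` months after (year, month); ``k`` may be negative."""
    m0 = year * 12 + (month - 1) + k
    return m0 // 12, m0 % 12 + 1


# ---------------------------------------------------------------- aggregates

def annual_mean_temperature(temps: pd.DataFrame, year: int) -> float:
    """Arithmetic mean of the 12 monthly temperatures of a calendar year."""
    sub = temps[temps["year"] == year]
    if len(sub) != 12 or set(sub["month"]) != set(range(1, 13)):
        raise CoverageError(f"year {year}: need all 12 months, found {sorted(sub['month'])}")
    return float(sub["temp_c"].mean())


def _annual_mean_map(temps: pd.DataFrame) -> dict[int, float]:
    out = {}
    for y, sub in temps.groupby("year"):
        if len(sub) == 12:
            out[int(y)] = float(sub["temp_c"].mean())
    return out


def assemble_model_frame(births: pd.DataFrame, temps: pd.DataFrame) -> pd.DataFrame:
    """One row per birth month with response and all temperature covariates.

    Columns: ``birth_year, birth_month, girls, total, conception_year,
    conception_month, temp_conception_year_mean, temp_birth_year_mean,
    temp_lag[-9] .. temp_lag[9]`` (lag 0 = conception month).

    Rows whose 19-month lag window or conception-year annual mean falls
    outside the temperature record are dropped; the dropped count is logged
    and stored in ``frame.attrs["n_dropped"]``.  ``temp_birth_year_mean`` may
    be NaN where the birth year is incompletely covered (it is only needed
    under the birth-year covariate convention).
    """
    births = validate_birth_series(births.copy())
    temps = validate_temperature_series(temps.copy())
    tmap = {(int(r.year), int(r.month)): float(r.temp_c) for r in temps.itertuples()}
    amap = _annual_mean_map(temps)

    rows, dropped = [], 0
    for r in births.itertuples():
        ce = estimate_conception(int(r.year), int(r.month))
        lagvals = {}
        ok = True
        for k in LAGS:
            ym = shift_month(ce.conception_year, ce.conception_month, k)
            v = tmap.get(ym)
            if v is None:
                ok = False
                break
            lagvals[f"temp_lag[{k}]"] = v
        cym = amap.get(ce.conception_year)
        if not ok or cym is None:
            dropped += 1
            continue
        rows.append(
            {
                "birth_year": int(r.year),
                "birth_month": int(r.month),
                "girls": int(r.girls),
                "total": int(r.boys) + int(r.girls),
                "conception_year": ce.conception_year,
                "conception_month": ce.conception_month,
                "temp_conception_year_mean": cym,
                "temp_birth_year_mean": amap.get(int(r.year), np.nan),
                **lagvals,
            }
        )
    if not rows:
        raise CoverageError("no birth month has complete temperature coverage")
    frame = pd.DataFrame(rows)
    frame.attrs["n_dropped"] = dropped
    frame.attrs["n_input"] = len(births)
    if dropped:
        log.info("assemble_model_frame: dropped %d of %d birth months (incomplete temperature coverage)",
                 dropped, len(births))
    return frame
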