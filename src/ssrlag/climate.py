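"""Climatological characterization of a monthly temperature series.

Covers the station-series summaries used alongside the sex-ratio models:
per-month and annual means/standard deviations, the decadal linear trend with
its t-test, and the 11-class percentile thermal classification (thresholds at
the 5, 10, 20, 30, 40, 60, 70, 80, 90 and 95th percentiles of a reference
period, computed separately for each calendar month and for annual means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PERCENTILES = (5.0, 10.0, 20.0, 30.0, 40.0, 60.0, 70.0, 80.0, 90.0, 95.0)

#: Ordered labels of the 11 percentile bands (band 5 = 40th-60th = "normal").
CLASS_LABELS = (
    "extremely cold",
    "anomalously cold",
    "very cold",
    "cold",
    "light cold",
    "normal",
    "light warm",
    "warm",
    "very warm",
    "anomalously warm",
    "extremely warm",
)
NORMAL_CLASS = 5


@dataclass
class TrendResult:
    """OLS trend of annual mean temperature on calendar year."""

    slope_per_decade: float
    t_statistic: float
    p_value: float
    n_years: int

    @property
    def significant_at_005(self) -> bool:
        return self.p_value < 0.05


@dataclass
class ThermalClassification:
    """Percentile classes of one scope (annual or a single calendar month)."""

    scope: str                      # "annual" or "month-1".."month-12"
    thresholds: np.ndarray          # 10 non-decreasing °C values
    labels: pd.Series = field(repr=False)  # year -> class index 0..10

    def label_names(self) -> pd.Series:
        return self.labels.map(lambda i: CLASS_LABELS[i])


# ------------------------------------------------------------------ summary

def annual_means(temps: pd.DataFrame, warn_incomplete: bool = True) -> pd.Series:
    """Annual means over complete years (12 months present), indexed by year."""
    counts = temps.groupby("year")["month"].nunique()
    complete = counts[counts == 12].index
    skipped = counts.index.difference(complete)
    if len(skipped) and warn_incomplete:
        warnings.warn(f"excluding incomplete years from annual means: {list(skipped)}")
    sub = temps[temps["year"].isin(complete)]
    return sub.groupby("year")["temp_c"].mean()


def climatology_summary(temps: pd.DataFrame) -> dict:
    """Monthly and annual summary statistics of a temperature series.

    Returns a dict with ``monthly_mean``/``monthly_sd`` (12-value Series over
    calendar months), ``annual_means`` (Series over complete years), and the
    scalars ``overall_mean`` / ``annual_sd`` (mean and sd of the annual means).
    """
    if annual_means(temps, warn_incomplete=False).empty:
        raise ValueError("need at least one complete year")
    am = annual_means(temps)
    monthly = temps.groupby("month")["temp_c"]
    return {
        "monthly_mean": monthly.mean(),
        "monthly_sd": monthly.std(ddof=1).fillna(0.0),
        "annual_means": am,
        "overall_mean": float(am.mean()),
        "annual_sd": float(am.std(ddof=1)) if len(am) > 1 else 0.0,
    }


def linear_trend(annual: pd.Series) -> TrendResult:
    """OLS slope of annual mean on year (°C/decade) with a two-sided t-test."""
    if len(annual) < 3:
        raise ValueError("trend needs at least 3 annual values")
    res = stats.linregress(annual.index.to_numpy(float), annual.to_numpy(float))
    return TrendResult(
        slope_per_decade=float(res.slope * 10.0),
        t_statistic=float(res.slope / res.stderr) if res.stderr > 0 else np.inf,
        p_value=float(res.pvalue),
        n_years=len(annual),
    )


# ----------------------------------------------------------- classification

def percentile_thresholds(values, percentiles=PERCENTILES) -> np.ndarray:
    """Percentile thresholds by linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to compute percentiles from")
    q = np.asarray(percentiles, dtype=float)
    if np.any(q <= 0) or np.any(q >= 100) or np.any(np.diff(q) <= 0):
        raise ValueError("percentiles must be strictly increasing within (0, 100)")
    return np.percentile(values, q, method="linear")


def classify_values(values: pd.Series, thresholds: np.ndarray) -> pd.Series:
    """Class index 0..len(thresholds) for each value.

    Intervals are upper-closed (a value equal to a threshold joins the band
    below it); where consecutive thresholds tie, the middle of the collapsed
    bands is assigned, so an all-constant series lands in the central class.
    """
    v = values.to_numpy(dtype=float)
    lo = np.searchsorted(thresholds, v, side="left")   # thresholds strictly below
    hi = np.searchsorted(thresholds, v, side="right")  # thresholds <= value
    return pd.Series((lo + hi) // 2, index=values.index)


def classify_thermal(
    temps: pd.DataFrame,
    reference_period: tuple[int, int] | None = None,
) -> dict[str, ThermalClassification]:
    """Percentile thermal classes for the annual scope and each calendar month.

    Thresholds come from the reference period (default: all complete years of
    the series); every year of the series then receives exactly one class per
    scope.  Returns a dict keyed by scope name.
    """
    am = annual_means(temps, warn_incomplete=False)
    if am.empty:
        raise ValueError("need at least one complete year")
    if reference_period is None:
        reference_period = (int(am.index.min()), int(am.index.max()))
    y0, y1 = reference_period
    ref_years = [y for y in am.index if y0 <= y <= y1]
    if not ref_years:
        raise ValueError(f"reference period {reference_period} not covered")

    out: dict[str, ThermalClassification] = {}
    thr = percentile_thresholds(am.loc[ref_years].to_numpy())
    out["annual"] = ThermalClassification("annual", thr, classify_values(am, thr))
    for m in range(1, 13):
        sub = temps[temps["month"] == m].set_index("year")["temp_c"].sort_index()
        ref = sub[(sub.index >= y0) & (sub.index <= y1)]
        if ref.empty:
            continue
        thr = percentile_thresholds(ref.to_numpy())
        out[f"month-{m}"] = ThermalClassification(f"month-{m}", thr, classify_values(sub, thr))
    return out


def classification_table(classes: dict[str, ThermalClassification]) -> pd.DataFrame:
    """Heat-map-style table: rows = scopes, columns = years, cells = class index."""
    rows = {scope: cl.labels for scope, cl in classes.items()}
    table = pd.DataFrame(rows).T
    table.index.name = "scope"
    return table.sort_index(axis=1)
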