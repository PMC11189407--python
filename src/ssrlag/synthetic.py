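"""Synthetic temperature and sex-at-birth series with known ground truth.

The generator mirrors the structure of the fitted models so that every
downstream stage (frame assembly, GAM, distributed lag, classification) can be
tested against a known truth:

* monthly mean temperature = climatological month mean + linear warming trend
  + independent Gaussian noise with a month-specific standard deviation
  (an optional AR(1) knob exists but defaults off — the models treat
  temperature as an exogenous covariate);
* monthly girl counts ~ Binomial(births, inverse-logit(eta)) with

      eta = baseline + trend(birth_year) + season[birth_month]
            + sum_l lag_profile[l] * temp(conception month + l).

The default climatology is calibrated to a 19th-century mid-European station
(annual mean ~7.5 °C, January ~−3.0 °C, July ~18.1 °C, weak warming of
0.1 °C/decade); the default lag profile is a cubic in the lag index with a
trough of ~−0.0045 logit/°C near lag −4 and ~+0.0065 at lag +9, matching the
order of magnitude of the real-data lag estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_data import (
    CoverageError,
    estimate_conception,
    shift_month,
    validate_temperature_series,
)

__all__ = [
    "ClimatologyProfile",
    "ScenarioConfig",
    "poznan_like_profile",
    "default_lag_profile",
    "default_scenario",
    "simulate_temperature",
    "true_linear_predictor",
    "simulate_birth_series",
]

N_LAGS = 19
LAGS = np.arange(-9, 10)


@dataclass(frozen=True)
class ClimatologyProfile:
    """Monthly climatology plus a linear trend, defining the generator."""

    monthly_means: tuple[float, ...]
    monthly_sds: tuple[float, ...]
    trend_per_decade: float = 0.0
    start_year: int = 1848
    end_year: int = 1900
    ar1: float = 0.0  # optional month-to-month noise autocorrelation

    def __post_init__(self) -> None:
        if len(self.monthly_means) != 12 or len(self.monthly_sds) != 12:
            raise ValueError("profile needs 12 monthly means and 12 sds")
        if any(s < 0 for s in self.monthly_sds):
            raise ValueError("monthly sds must be non-negative")
        if self.end_year < self.start_year:
            raise ValueError(f"invalid year range {self.start_year}..{self.end_year}")
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("ar1 must lie in (-1, 1)")

    @property
    def annual_mean(self) -> float:
        return float(np.mean(self.monthly_means))


def poznan_like_profile(**overrides) -> ClimatologyProfile:
    """Climatology anchored to the published station summaries.

    January −3.0 °C, February/December −1.6 °C, July 18.1 °C; the remaining
    months are plausible mid-European values chosen so the annual mean is
    ~7.5 °C.  Noise sds run from 3.0 °C in mid-winter to 1.2 °C in August;
    the warming trend is 0.1 °C/decade.  Month-to-month noise correlation of
    0.4 reproduces the published year-to-year spread of annual means
    (~0.8 °C), which independent monthly noise with these sds cannot.
    """
    kw = dict(
        monthly_means=(-3.0, -1.6, 2.0, 7.0, 12.5, 16.8, 18.1, 17.0, 13.0, 7.8, 2.3, -1.6),
        monthly_sds=(3.0, 3.0, 2.2, 1.6, 1.5, 1.4, 1.3, 1.2, 1.3, 1.5, 2.0, 2.6),
        trend_per_decade=0.1,
        start_year=1848,
        end_year=1900,
        ar1=0.4,
    )
    kw.update(overrides)
    return ClimatologyProfile(**kw)


def default_lag_profile() -> np.ndarray:
    """Cubic ground-truth lag profile (logit/°C) at lags −9..+9.

    Interpolates (−9, 0.0010), (−4, −0.0045), (0, −0.0020), (9, 0.0065): a
    pre-conception cooling trough with a positive late-pregnancy edge, on the
    ±0.005 scale of the real-data estimates.
    """
    anchors_x = np.array([-9.0, -4.0, 0.0, 9.0])
    anchors_y = np.array([0.0010, -0.0045, -0.0020, 0.0065])
    coef = np.polyfit(anchors_x, anchors_y, 3)
    return np.polyval(coef, LAGS.astype(float))


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth generative scenario for the girl-probability series."""

    lag_profile_true: tuple[float, ...] = tuple(np.zeros(N_LAGS))
    trend_shape: Callable[[float], float] | None = None  # year -> logit offset
    season_shape: tuple[float, ...] = tuple(np.zeros(12))  # birth month -> logit
    baseline_logit: float = -0.0556
    births_per_month: int | Sequence[int] = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lag_profile_true) != N_LAGS:
            raise ValueError(f"lag_profile_true needs {N_LAGS} entries (lags -9..+9)")
        if len(self.season_shape) != 12:
            raise ValueError("season_shape needs 12 entries")
        bp = self.births_per_month
        if np.isscalar(bp):
            if bp < 1:
                raise ValueError("births_per_month must be >= 1")
        elif np.any(np.asarray(bp) < 1):
            raise ValueError("births_per_month must be >= 1")


def default_scenario(**overrides) -> ScenarioConfig:
    """Study-scale default: cubic lag profile, no trend/season, ~100 births/month."""
    kw = dict(
        lag_profile_true=tuple(default_lag_profile()),
        baseline_logit=-0.0556,
        births_per_month=100,
        seed=0,
    )
    kw.update(overrides)
    return ScenarioConfig(**kw)


# ------------------------------------------------------------------ weather

def simulate_temperature(profile: ClimatologyProfile, seed: int) -> pd.DataFrame:
    """Monthly temperature series over the profile's year range.

    value(y, m) = monthly_mean[m] + trend_per_decade * (y - mid_year) / 10
                  + noise, with noise iid N(0, sd[m]) (or AR(1) across months
    when ``profile.ar1`` is set; marginal variance is preserved).  The trend
    is centred on the middle of the period so the monthly means keep their
    meaning as period means.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(profile.start_year, profile.end_year + 1)
    yy = np.repeat(years, 12)
    mm = np.tile(np.arange(1, 13), years.size)
    sds = np.asarray(profile.monthly_sds)[mm - 1]
    eps = rng.standard_normal(yy.size)
    if profile.ar1 != 0.0:
        z = np.empty_like(eps)
        z[0] = eps[0]
        a = profile.ar1
        for i in range(1, eps.size):
            z[i] = a * z[i - 1] + np.sqrt(1.0 - a * a) * eps[i]
        eps = z
    mid_year = 0.5 * (profile.start_year + profile.end_year)
    temp = (
        np.asarray(profile.monthly_means)[mm - 1]
        + profile.trend_per_decade * (yy - mid_year) / 10.0
        + sds * eps
    )
    return validate_temperature_series(pd.DataFrame({"year": yy, "month": mm, "temp_c": temp}))


# ------------------------------------------------------------------- births

def true_linear_predictor(scenario: ScenarioConfig, frame_row) -> float:
    """Ground-truth logit for one model-frame row (the generative analogue of
    the fitted model's linear predictor)."""
    lagsum = 0.0
    for j, l in enumerate(LAGS):
        key = f"temp_lag[{l}]"
        try:
            v = frame_row[key]
        except (KeyError, IndexError) as exc:
            raise ValueError(f"frame row lacks {key}") from exc
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"frame row lacks {key}")
        lagsum += scenario.lag_profile_true[j] * float(v)
    trend = scenario.trend_shape(float(frame_row["birth_year"])) if scenario.trend_shape else 0.0
    season = scenario.season_shape[int(frame_row["birth_month"]) - 1]
    return float(scenario.baseline_logit + trend + season + lagsum)


def _lag_window(temps_map, birth_year, birth_month):
    ce = estimate_conception(birth_year, birth_month)
    vals = {}
    for l in LAGS:
        ym = shift_month(ce.conception_year, ce.conception_month, int(l))
        if ym not in temps_map:
            return None, ym
        vals[f"temp_lag[{l}]"] = temps_map[ym]
    return vals, None


def simulate_birth_series(
    temps: pd.DataFrame,
    scenario: ScenarioConfig,
    birth_years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Monthly (boys, girls) counts driven by the scenario's ground truth.

    Birth months default to every month whose full −9..+9 lag window lies
    inside the temperature record; an explicit ``birth_years`` range raises a
    coverage error naming the first missing (year, month) instead.
    """
    tmap = {(int(r.year), int(r.month)): float(r.temp_c) for r in temps.itertuples()}
    if birth_years is None:
        y0, y1 = int(temps["year"].min()), int(temps["year"].max())
        candidates = [(y, m) for y in range(y0, y1 + 1) for m in range(1, 13)]
        strict = False
    else:
        candidates = [(y, m) for y in range(birth_years[0], birth_years[1] + 1) for m in range(1, 13)]
        strict = True

    rng = np.random.default_rng(scenario.seed)
    bp = scenario.births_per_month
    rows = []
    for i, (y, m) in enumerate(candidates):
        vals, missing = _lag_window(tmap, y, m)
        if vals is None:
            if strict:
                raise CoverageError(
                    f"temperature record lacks {missing} needed for births in {y}-{m:02d}"
                )
            continue
        row = {"birth_year": y, "birth_month": m, **vals}
        p = expit(true_linear_predictor(scenario, row))
        n = int(bp if np.isscalar(bp) else np.asarray(bp)[i % len(bp)])
        girls = int(rng.binomial(n, p))
        rows.append({"year": y, "month": m, "boys": n - girls, "girls": girls})
    if not rows:
        raise CoverageError("temperature record covers no complete lag window")
    return pd.DataFrame(rows)
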