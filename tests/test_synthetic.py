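"""Synthetic-data generator: determinism, degenerate cases, convergence."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ssrlag.io_data import CoverageError
from ssrlag.synthetic import (
    ClimatologyProfile,
    ScenarioConfig,
    default_lag_profile,
    default_scenario,
    poznan_like_profile,
    simulate_birth_series,
    simulate_temperature,
    true_linear_predictor,
)


# ------------------------------------------------------------- temperature

def test_noise_free_profile_reproduces_means_exactly():
    prof = ClimatologyProfile(
        monthly_means=(-3.0,) + (5.0,) * 11, monthly_sds=(0.0,) * 12, trend_per_decade=0.0
    )
    t = simulate_temperature(prof, seed=1)
    assert (t.loc[t["month"] == 1, "temp_c"] == -3.0).all()
    assert (t.loc[t["month"] != 1, "temp_c"] == 5.0).all()


def test_linear_trend_arithmetic():
    prof = ClimatologyProfile(
        monthly_means=(7.0,) * 12, monthly_sds=(0.0,) * 12,
        trend_per_decade=1.0, start_year=1848, end_year=1900,
    )
    t = simulate_temperature(prof, seed=0)
    d = t.loc[t["year"] == 1898, "temp_c"].to_numpy() - t.loc[t["year"] == 1848, "temp_c"].to_numpy()
    np.testing.assert_allclose(d, 5.0)


def test_no_missing_cells_and_determinism(profile):
    t1 = simulate_temperature(profile, seed=9)
    t2 = simulate_temperature(profile, seed=9)
    pd.testing.assert_frame_equal(t1, t2)
    assert len(t1) == 53 * 12
    assert not t1.duplicated(subset=["year", "month"]).any()
    t3 = simulate_temperature(profile, seed=10)
    assert not t1["temp_c"].equals(t3["temp_c"])


def test_monte_carlo_mean_matches_profile():
    """Sample mean of annual means sits within 3 SE of the analytic mean."""
    prof = poznan_like_profile(start_year=1, end_year=10_000, trend_per_decade=0.0)
    t = simulate_temperature(prof, seed=2)
    annual = t.groupby("year")["temp_c"].mean()
    se = np.sqrt(np.mean(np.array(prof.monthly_sds) ** 2) / 12 / len(annual))
    assert abs(annual.mean() - prof.annual_mean) < 3 * se


def test_ar1_preserves_marginal_sd():
    prof = poznan_like_profile(start_year=1, end_year=3000, ar1=0.5, trend_per_decade=0.0)
    t = simulate_temperature(prof, seed=4)
    jan = t.loc[t["month"] == 7, "temp_c"]
    assert jan.std() == pytest.approx(prof.monthly_sds[6], rel=0.1)


def test_profile_validation():
    with pytest.raises(ValueError, match="12 monthly"):
        ClimatologyProfile(monthly_means=(1.0,) * 11, monthly_sds=(1.0,) * 12)
    with pytest.raises(ValueError, match="non-negative"):
        ClimatologyProfile(monthly_means=(1.0,) * 12, monthly_sds=(-1.0,) * 12)
    with pytest.raises(ValueError, match="year range"):
        ClimatologyProfile(monthly_means=(1.0,) * 12, monthly_sds=(1.0,) * 12,
                           start_year=1900, end_year=1848)


# --------------------------------------------------------- linear predictor

def _row(**kw):
    row = {"birth_year": 1850, "birth_month": 6}
    row.update({f"temp_lag[{k}]": 0.0 for k in range(-9, 10)})
    row.update(kw)
    return row


def test_all_zero_scenario_gives_zero():
    sc = ScenarioConfig(baseline_logit=0.0)
    assert true_linear_predictor(sc, _row()) == 0.0


def test_single_lag_product():
    profile = np.zeros(19)
    profile[9] = 0.01  # lag 0
    sc = ScenarioConfig(lag_profile_true=tuple(profile), baseline_logit=0.0)
    assert true_linear_predictor(sc, _row(**{"temp_lag[0]": 10.0})) == pytest.approx(0.1)


def test_predictor_matches_brute_force_sum():
    rng = np.random.default_rng(6)
    profile = rng.normal(scale=0.005, size=19)
    season = rng.normal(scale=0.01, size=12)
    sc = ScenarioConfig(
        lag_profile_true=tuple(profile),
        season_shape=tuple(season),
        trend_shape=lambda y: 0.002 * (y - 1874),
        baseline_logit=-0.05,
    )
    temps = rng.normal(7.0, 5.0, size=19)
    row = _row(**{f"temp_lag[{k}]": temps[j] for j, k in enumerate(range(-9, 10))})
    expected = -0.05 + 0.002 * (1850 - 1874) + season[5]
    for j in range(19):  # independent brute-force summation
        expected += profile[j] * temps[j]
    assert true_linear_predictor(sc, row) == pytest.approx(expected, abs=1e-12)


def test_predictor_rejects_missing_lag():
    row = _row()
    del row["temp_lag[-4]"]
    with pytest.raises(ValueError, match=r"temp_lag\[-4\]"):
        true_linear_predictor(ScenarioConfig(), row)


# ------------------------------------------------------------------- births

def test_counts_sum_to_births_per_month(births, scenario):
    assert ((births["boys"] + births["girls"]) == scenario.births_per_month).all()


def test_same_seed_is_bitwise_identical(temps, scenario):
    b1 = simulate_birth_series(temps, scenario)
    b2 = simulate_birth_series(temps, scenario)
    pd.testing.assert_frame_equal(b1, b2)


def test_null_scenario_girl_fraction(temps):
    sc = ScenarioConfig(baseline_logit=0.0, births_per_month=2000, seed=3)
    b = simulate_birth_series(temps, sc)
    total = (b["boys"] + b["girls"]).sum()
    frac = b["girls"].sum() / total
    assert total > 1e6
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / total)


def test_baseline_logit_reproduces_pooled_proportion(temps):
    sc = ScenarioConfig(baseline_logit=-0.0556, births_per_month=3000, seed=5)
    b = simulate_birth_series(temps, sc)
    frac = b["girls"].sum() / (b["boys"] + b["girls"]).sum()
    assert frac == pytest.approx(expit(-0.0556), abs=0.002)  # ~0.4861


def test_monthly_proportion_converges_to_inverse_logit(temps):
    """Per-month girl fraction matches the truth within 4 SE at n = 1e5."""
    sc = default_scenario(births_per_month=100_000, seed=12)
    b = simulate_birth_series(temps, sc).head(24)
    from ssrlag.io_data import assemble_model_frame

    frame = assemble_model_frame(b, temps)
    for _, row in frame.iterrows():
        p = expit(true_linear_predictor(sc, row))
        obs = row["girls"] / row["total"]
        se = np.sqrt(p * (1 - p) / row["total"])
        assert abs(obs - p) < 4 * se


def test_explicit_range_raises_named_coverage_error(temps):
    with pytest.raises(CoverageError, match=r"1848"):
        simulate_birth_series(temps, default_scenario(), birth_years=(1848, 1850))


def test_scenario_validation():
    with pytest.raises(ValueError, match="19 entries"):
        ScenarioConfig(lag_profile_true=(0.0,) * 18)
    with pytest.raises(ValueError, match="12 entries"):
        ScenarioConfig(season_shape=(0.0,) * 11)
    with pytest.raises(ValueError, match="births_per_month"):
        ScenarioConfig(births_per_month=0)


def test_default_lag_profile_shape():
    prof = default_lag_profile()
    assert prof.shape == (19,)
    lags = np.arange(-9, 10)
    assert prof[lags == -4] == pytest.approx(-0.0045)
    assert prof[lags == 9] == pytest.approx(0.0065)
    assert np.abs(prof).max() < 0.01  # realistic effect scale, logit per degree C
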