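"""GAM engine: PIRLS, oracles, edf, penalization limits, effect curves."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import logit

from ssrlag.gam import GamModel, binomial_deviance


def test_intercept_only_matches_closed_form():
    """The fitted intercept is the logit of the pooled girl proportion."""
    y, n = np.array([32087.0]), np.array([66009.0])
    fit = GamModel().add_intercept().fit(y, n)
    assert fit.beta[0] == pytest.approx(logit(32087.0 / 66009.0), abs=1e-8)
    assert fit.beta[0] == pytest.approx(-0.0556, abs=5e-5)


def test_intercept_only_on_many_rows(frame, response):
    y, n = response
    fit = GamModel().add_intercept().fit(y, n)
    assert fit.beta[0] == pytest.approx(logit(y.sum() / n.sum()), abs=1e-8)
    assert fit.edf_total == pytest.approx(1.0, abs=1e-8)


def test_unpenalized_fit_matches_glm_oracle(frame, response):
    """lambda=0, no shrinkage: identical to an independent logistic regression."""
    y, n = response
    m = GamModel().add_intercept()
    m.add_linear("temp", frame["temp_conception_year_mean"].to_numpy())
    m.add_smooth("birth_year", frame["birth_year"].to_numpy(float), k=6, shrinkage=False)
    fit = m.fit(y, n, lam=0.0)
    X = m._design(len(y))
    oracle = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-6)
    assert fit.deviance == pytest.approx(oracle.deviance, abs=1e-6)


def test_heavy_penalty_shrinks_to_intercept_only(frame, response):
    y, n = response
    m = GamModel().add_intercept()
    m.add_smooth("birth_year", frame["birth_year"].to_numpy(float), k=8, shrinkage=True)
    fit = m.fit(y, n, lam=1e12)
    fit0 = GamModel().add_intercept().fit(y, n)
    assert fit.beta[0] == pytest.approx(fit0.beta[0], abs=1e-4)
    assert abs(fit.coef_block("birth_year")).max() < 1e-4
    assert fit.edf("birth_year") < 1e-3
    assert fit.deviance == pytest.approx(fit0.deviance, rel=1e-5)


def test_parametric_edf_is_one(frame, response):
    y, n = response
    m = GamModel().add_intercept()
    m.add_linear("temp", frame["temp_conception_year_mean"].to_numpy())
    m.add_smooth("birth_year", frame["birth_year"].to_numpy(float), k=6)
    fit = m.fit(y, n)
    assert fit.edf("intercept") == pytest.approx(1.0, abs=1e-6)
    assert fit.edf("temp") == pytest.approx(1.0, abs=1e-6)


def test_edf_additivity_and_bounds(frame, response):
    y, n = response
    m = GamModel().add_intercept()
    m.add_smooth("birth_year", frame["birth_year"].to_numpy(float), k=7)
    m.add_smooth("birth_month", frame["birth_month"].to_numpy(float), k=6, cyclic=True, period=12.0)
    fit = m.fit(y, n)
    total = sum(fit.edf(t) for t in fit.term_names)
    assert total == pytest.approx(fit.edf_total, abs=1e-8)
    assert fit.edf("birth_year") <= 7 and fit.edf("birth_month") <= 6
    assert fit.edf_total <= len(fit.beta)


def test_edf_monotone_in_lambda(frame, response):
    """Total edf is non-increasing as any one lambda grows."""
    y, n = response
    m = GamModel().add_intercept()
    m.add_smooth("birth_year", frame["birth_year"].to_numpy(float), k=8)
    base = np.array([1.0, 1.0])
    edfs = []
    for mult in (1.0, 10.0, 100.0, 1e4):
        lam = base.copy()
        lam[0] *= mult
        edfs.append(m.fit(y, n, lam=lam).edf_total)
    assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))


def test_aggregation_invariance(small_frame):
    """Grouped (girls, total) fit equals the exploded per-birth 0/1 fit."""
    sub = small_frame.head(40)
    y = sub["girls"].to_numpy(float)
    n = sub["total"].to_numpy(float)
    x = sub["temp_conception_year_mean"].to_numpy()

    m1 = GamModel().add_intercept().add_linear("t", x)
    f1 = m1.fit(y, n, lam=0.0)

    reps = n.astype(int)
    y_long, x_long = [], []
    for yi, ni, xi in zip(y.astype(int), reps, x):
        y_long += [1] * yi + [0] * (ni - yi)
        x_long += [xi] * ni
    m2 = GamModel().add_intercept().add_linear("t", np.array(x_long))
    f2 = m2.fit(np.array(y_long, float), np.ones(len(y_long)))
    np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-6)


def test_selected_lambda_is_local_minimum(frame, response):
    """The criterion at the returned lambdas beats random perturbations."""
    y, n = response
    m = GamModel().add_intercept()
    m.add_smooth("birth_year", frame["birth_year"].to_numpy(float), k=6)

    def reml_at(lam):
        fit = m.fit(y, n, lam=lam)
        Ss = m._embed_penalties()
        Slam = sum(l * S for l, S in zip(lam, Ss))
        W = n * fit.fitted_probabilities * (1 - fit.fitted_probabilities)
        X = m._design(len(y))
        H = (X * W[:, None]).T @ X
        A = H + Slam
        pen = float(fit.beta @ Slam @ fit.beta)
        logdetA = float(np.linalg.slogdet(A)[1])
        w = np.linalg.eigvalsh(sum(l * S for l, S in zip(lam, Ss))[1:, 1:])
        logdetS = float(np.log(w[w > 1e-9 * w.max()]).sum())
        return 0.5 * (fit.deviance + pen) + 0.5 * logdetA - 0.5 * logdetS

    fit = m.fit(y, n, criterion="reml")
    best = reml_at(fit.lam)
    rng = np.random.default_rng(5)
    # the criterion flattens toward its lambda -> inf asymptote once a term is
    # fully shrunk, so near-ties below 0.01 are numerically indistinguishable
    for _ in range(10):
        lam_pert = fit.lam * np.exp(rng.uniform(-1.5, 1.5, size=fit.lam.size))
        assert best <= reml_at(lam_pert) + 1e-2


def test_smooth_pvalue_in_unit_interval(frame, response):
    y, n = response
    m = GamModel().add_intercept()
    m.add_smooth("birth_year", frame["birth_year"].to_numpy(float), k=6)
    fit = m.fit(y, n)
    stat, df, p = fit.smooth_test("birth_year")
    assert stat >= 0 and df >= 1
    assert 0.0 <= p <= 1.0
    with pytest.raises(KeyError):
        fit.smooth_test("nope")


def test_effect_curve_centring_and_band_width(temps, profile):
    """Effect curves are centred; bands narrow as the sample grows."""
    from ssrlag import assemble_model_frame, default_scenario, simulate_birth_series
    from ssrlag.pipeline import fit_MT0

    widths = {}
    for bpm in (100, 1000):
        sc = default_scenario(seed=17, births_per_month=bpm)
        frame = assemble_model_frame(simulate_birth_series(temps, sc), temps)
        fit = fit_MT0(frame)
        x = frame["temp_conception_year_mean"].to_numpy()
        eff, lo, hi = fit.predict_effect("annual_temperature", x)
        assert abs(eff.mean()) < 1e-9
        assert np.all(lo <= eff) and np.all(eff <= hi)
        widths[bpm] = np.mean(hi - lo)
    assert widths[1000] < widths[100]


def test_probability_scale_prediction(frame, response):
    y, n = response
    from ssrlag.pipeline import fit_M0

    fit = fit_M0(frame, k_year=6, k_month=5)
    grid = np.linspace(frame["birth_year"].min(), frame["birth_year"].max(), 20)
    p, lo, hi = fit.predict_effect("birth_year", grid, scale="probability")
    assert np.all((0 < lo) & (lo <= p) & (p <= hi) & (hi < 1))


def test_response_validation(frame, response):
    y, n = response
    with pytest.raises(ValueError, match="successes"):
        GamModel().add_intercept().fit(n, y)  # successes > totals


def test_deviance_zero_at_saturation():
    y = np.array([3.0, 0.0, 5.0])
    n = np.array([10.0, 4.0, 5.0])
    assert binomial_deviance(y, n, y / n) == pytest.approx(0.0, abs=1e-10)
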