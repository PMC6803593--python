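"""ALDVMM observation model: likelihood, propriety, limits, prediction."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from kdqolmap.models import (aldvmm_loglik, fit_aldvmm, fit_ols,
                             predict_aldvmm)
from kdqolmap.models.aldvmm import ALDVMMParams
from kdqolmap.valuesets import ValueSet, DIMENSIONS


def _wide_valueset():
    """Additive 3L set with extreme bounds so censoring never binds."""
    return ValueSet("wide", "3L", constant=0.0,
                    decrements={d: (1e-9, 10.0) for d in DIMENSIONS})


def _params(betas, sigmas, delta, y_min, psi):
    return ALDVMMParams(np.atleast_2d(np.asarray(betas, float)),
                        np.atleast_1d(np.asarray(sigmas, float)),
                        np.atleast_1d(np.asarray(delta, float)),
                        y_min, psi, converged=True)


def test_single_component_wide_bounds_equals_gaussian_loglik():
    rng = np.random.default_rng(0)
    n = 200
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    beta = np.array([0.3, 0.2])
    sigma = 0.25
    y = X @ beta + sigma * rng.normal(size=n)
    p = _params(beta, sigma, [], y_min=-50.0, psi=50.0)
    ll = aldvmm_loglik(p, X, y)
    resid = y - X @ beta
    gauss = norm.logpdf(resid, scale=sigma).sum()
    assert ll == pytest.approx(gauss, abs=1e-8)


def test_density_propriety_by_quadrature(vs3):
    """Point masses plus the interior integral must total 1."""
    y_min, psi = vs3.floor, vs3.truncation_point
    for mu, sigma in [(0.6, 0.2), (1.2, 0.1), (-0.8, 0.4), (0.85, 0.05),
                      (0.0, 1.0)]:
        mass = norm.sf((psi - mu) / sigma) + norm.cdf((y_min - mu) / sigma)
        integral, _ = integrate.quad(
            lambda y: norm.pdf((y - mu) / sigma) / sigma, y_min, psi,
            epsabs=1e-12)
        assert mass + integral == pytest.approx(1.0, abs=1e-8)


def test_label_degeneracy_two_equal_components(vs3):
    rng = np.random.default_rng(1)
    n = 100
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    beta = np.array([0.5, 0.3])
    y = np.clip(X @ beta + 0.2 * rng.normal(size=n), vs3.floor, 1.0)
    y[y > vs3.truncation_point] = 1.0
    one = _params(beta, 0.2, [], vs3.floor, vs3.truncation_point)
    two = _params([beta, beta], [0.2, 0.2], [0.0], vs3.floor,
                  vs3.truncation_point)
    assert aldvmm_loglik(two, X, y) == pytest.approx(
        aldvmm_loglik(one, X, y), abs=1e-10)


def test_loglik_rejects_gap_observations(vs3):
    p = _params([0.5], 0.2, [], vs3.floor, vs3.truncation_point)
    X = np.ones((1, 1))
    with pytest.raises(ValueError, match="gap"):
        aldvmm_loglik(p, X, np.array([0.95]))


def test_prediction_limits(vs3):
    X = np.ones((1, 1))
    hi = _params([10.0], 0.1, [], vs3.floor, vs3.truncation_point)
    lo = _params([-10.0], 0.1, [], vs3.floor, vs3.truncation_point)
    assert predict_aldvmm(hi, X)[0] == pytest.approx(1.0, abs=1e-12)
    assert predict_aldvmm(lo, X)[0] == pytest.approx(vs3.floor, abs=1e-12)


def test_prediction_matches_monte_carlo(vs3):
    """Closed-form E[y|x] vs simulation of the observation model."""
    rng = np.random.default_rng(2)
    y_min, psi = vs3.floor, vs3.truncation_point
    settings = [(0.6, 0.2), (0.9, 0.3), (0.2, 0.5), (1.0, 0.15), (-0.2, 0.3)]
    for mu, sigma in settings:
        p = _params([mu], sigma, [], y_min, psi)
        exact = predict_aldvmm(p, np.ones((1, 1)))[0]
        draws = mu + sigma * rng.standard_normal(10 ** 6)
        sim = np.where(draws >= psi, 1.0, np.clip(draws, y_min, None))
        se = sim.std() / 1000
        assert abs(exact - sim.mean()) < 3 * se + 1e-6


def test_c1_interior_data_close_to_ols():
    """With wide bounds and interior-only data, ALDVMM C=1 is Gaussian ML."""
    rng = np.random.default_rng(3)
    n = 500
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    beta = np.array([0.3, 0.1])
    y = X @ beta + 0.05 * rng.normal(size=n)   # stays well inside the bounds
    vs = _wide_valueset()
    fit = fit_aldvmm(X, y, vs, 1, n_starts=3, seed=0)
    ols = fit_ols(X, y)
    assert fit.converged
    assert np.allclose(fit.betas[0], ols.coefficients, atol=1e-3)


def test_predictions_bounded_for_any_inputs(vs3, aldvmm_dataset):
    df, sidecar = aldvmm_dataset
    p = ALDVMMParams.from_dict(sidecar["true_params"])
    rng = np.random.default_rng(4)
    X = np.column_stack([np.ones(200), rng.uniform(-2, 2, (200, 2))])
    pred = predict_aldvmm(p, X)
    assert np.all(pred >= vs3.floor - 1e-12)
    assert np.all(pred <= 1.0 + 1e-12)


def test_component_reporting_sorted_by_intercept(vs3, aldvmm_dataset):
    df, _ = aldvmm_dataset
    X = np.column_stack([np.ones(len(df)), df.kdcs / 100, df.age / 10])
    y = df.eq5d_index.to_numpy()
    fit = fit_aldvmm(X, y, vs3, 2, n_starts=4, seed=1)
    assert fit.betas[0, 0] <= fit.betas[1, 0]
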