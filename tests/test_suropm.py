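"""Joint ordered-probit response mapping: GHK oracles and prediction."""

import numpy as np
import pytest
from scipy.stats import norm

from kdqolmap.models import (predict_state_probs, predict_utility_response,
                             suropm_loglik, fit_suropm)
from kdqolmap.models.suropm import SUROPMParams, _fitted_states
from kdqolmap.synthetic import _dgp_design
from kdqolmap.valuesets import enumerate_states


def _identity_params(params: SUROPMParams) -> SUROPMParams:
    d = params.to_dict()
    d["correlation_matrix"] = np.eye(5).tolist()
    return SUROPMParams.from_dict(d)


def test_independent_loglik_matches_probit_product(true_suropm,
                                                   response_dataset):
    """With R = I the GHK likelihood equals the product of five univariate
    ordered-probit likelihoods (the key correctness oracle)."""
    df, _ = response_dataset
    X = _dgp_design(df, "response")
    resp = df[["mo", "sc", "ua", "pd", "ad"]].to_numpy(dtype=int)
    pI = _identity_params(true_suropm)
    ll = suropm_loglik(pI, X, resp)
    manual = 0.0
    for d in range(5):
        kappa = np.concatenate([[-np.inf], pI.cutpoints[d], [np.inf]])
        xb = X @ pI.thetas[d]
        manual += np.log(norm.cdf(kappa[resp[:, d]] - xb)
                         - norm.cdf(kappa[resp[:, d] - 1] - xb)).sum()
    assert abs(ll - manual) < 1e-6 * len(df)


def test_single_dimension_closed_form():
    """κ=(−1,1), θ=0: level probabilities Φ(−1), Φ(1)−Φ(−1), 1−Φ(1)."""
    p = SUROPMParams(np.zeros((5, 1)), [np.array([-1.0, 1.0])] * 5,
                     np.eye(5), 3, converged=True)
    probs = predict_state_probs(p, np.zeros((1, 1)))[0]
    combos, _ = _fitted_states(p)
    marg = np.array([probs[combos[:, 0] == lev].sum() for lev in (1, 2, 3)])
    expected = [norm.cdf(-1), norm.cdf(1) - norm.cdf(-1), norm.sf(1)]
    assert np.allclose(marg, expected, atol=1e-9)


def test_state_probs_factorize_when_independent(true_suropm):
    pI = _identity_params(true_suropm)
    x = np.array([[0.66, 6.6]])
    probs = predict_state_probs(pI, x)[0]
    combos, _ = _fitted_states(pI)
    marginals = []
    for d in range(5):
        kappa = np.concatenate([[-np.inf], pI.cutpoints[d], [np.inf]])
        xb = float(x[0] @ pI.thetas[d])
        marginals.append(norm.cdf(kappa[1:] - xb) - norm.cdf(kappa[:-1] - xb))
    expected = np.ones(len(combos))
    for d in range(5):
        expected *= marginals[d][combos[:, d] - 1]
    assert np.allclose(probs, expected, atol=1e-6)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(probs >= 0)


def test_extreme_health_concentrates_on_full_health(true_suropm):
    # limiting case: a health index far beyond the cutpoints on every item
    x = np.array([[3.0, 0.5]])
    probs = predict_state_probs(true_suropm, x)[0]
    assert probs[0] > 0.95                      # state (1,1,1,1,1) is first
    assert probs[0] == probs.max()


def test_uniform_probs_mean_utility(vs3):
    """θ=0 with tertile cutpoints makes all 243 states equally likely."""
    k = norm.ppf([1 / 3, 2 / 3])
    p = SUROPMParams(np.zeros((5, 1)), [k.copy() for _ in range(5)],
                     np.eye(5), 3, converged=True)
    eu = predict_utility_response(p, np.zeros((1, 1)), vs3)[0]
    allvals = np.array([vs3.index_of(s) for s in enumerate_states("3L")])
    assert eu == pytest.approx(allvals.mean(), abs=1e-9)


def test_expected_utility_bounds_and_per_record_valuesets(vs3, true_suropm,
                                                          response_dataset):
    df, _ = response_dataset
    X = _dgp_design(df, "response")[:20]
    eu = predict_utility_response(true_suropm, X, vs3)
    assert np.all((eu >= vs3.floor) & (eu <= 1.0))
    # per-record value sets: list of length n
    eu2 = predict_utility_response(true_suropm, X, [vs3] * 20)
    assert np.allclose(eu, eu2)


def test_value_set_version_mismatch(vs5, true_suropm):
    with pytest.raises(ValueError, match="version"):
        predict_utility_response(true_suropm, np.zeros((1, 2)), vs5)


def test_unobserved_level_errors_and_merge(response_dataset):
    df, _ = response_dataset
    X = _dgp_design(df, "response")
    resp = df[["mo", "sc", "ua", "pd", "ad"]].to_numpy(dtype=int)
    resp = resp.copy()
    resp[resp[:, 0] == 3, 0] = 2                # wipe out level 3 of item 0
    with pytest.raises(ValueError, match="level"):
        fit_suropm(X, resp, 3, n_draws=32, refine="none")
    fit = fit_suropm(X, resp, 3, n_draws=32, refine="none",
                     merge_levels={0: {3: 2}})
    assert fit.converged
    assert fit.level_values[0] == [1, 2]
    assert fit.level_values[1] == [1, 2, 3]


def test_ghk_seed_stability(response_dataset, true_suropm):
    """Simulated likelihood varies by < 0.1% across GHK seeds at 200 draws."""
    df, _ = response_dataset
    X = _dgp_design(df, "response")
    resp = df[["mo", "sc", "ua", "pd", "ad"]].to_numpy(dtype=int)
    d = true_suropm.to_dict()
    lls = []
    for seed in (0, 99):
        d["ghk"] = {"draws": 200, "seed": seed}
        lls.append(suropm_loglik(SUROPMParams.from_dict(d), X, resp))
    assert abs(lls[0] - lls[1]) / abs(lls[0]) < 1e-3
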