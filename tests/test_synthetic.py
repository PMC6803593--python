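"""Synthetic-data generator: moments, feasible support, determinism."""

import time

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from kdqolmap.models.aldvmm import ALDVMMParams
from kdqolmap.synthetic import (SyntheticConfig, _dgp_design,
                                default_true_suropm,
                                france_like_config, gen_covariates,
                                gen_dataset, gen_eq5d_aldvmm,
                                gen_eq5d_response, save_dataset)
from kdqolmap.kdqol import load_dataset


def test_covariate_moment_targets():
    df = gen_covariates(france_like_config(n=10_000, seed=1))
    # PCS/MCS are barely clipped: tight agreement with the targets
    assert df.pcs.mean() == pytest.approx(39.90, abs=0.5)
    assert df.mcs.mean() == pytest.approx(46.51, abs=0.5)
    assert df.pcs.std() == pytest.approx(10.09, abs=0.5)
    # heavily right-clipped subscales shift by a bounded, logged amount
    assert df.symptoms.mean() == pytest.approx(78.48, abs=2.5)
    assert df.effects.mean() == pytest.approx(70.55, abs=2.5)
    assert df.burden.mean() == pytest.approx(48.20, abs=2.5)
    assert (df.age >= 18).all()
    assert df.attrs["clip_rate"] < 0.15


def test_determinism_and_kdcs_identity():
    a = gen_covariates(france_like_config(n=500, seed=9))
    b = gen_covariates(france_like_config(n=500, seed=9))
    pd.testing.assert_frame_equal(a, b)
    assert np.array_equal(a.kdcs.to_numpy(),
                          ((a.symptoms + a.effects + a.burden) / 3).to_numpy())


def test_aldvmm_dgp_feasible_support(vs3, aldvmm_dataset):
    df, _ = aldvmm_dataset
    y = df.eq5d_index.to_numpy()
    psi = vs3.truncation_point
    assert not np.any((y > psi + 1e-12) & (y < 1 - 1e-12))   # empty gap
    assert np.all((y >= vs3.floor - 1e-12) & (y <= 1 + 1e-12))
    assert (y == 1).sum() > 0                                # ceiling atom


def test_aldvmm_dgp_ceiling_matches_analytic(vs3, true_aldvmm):
    df = gen_covariates(france_like_config(n=100_000, seed=3))
    X = _dgp_design(df, "aldvmm")
    y = gen_eq5d_aldvmm(X, true_aldvmm, np.random.default_rng(4))
    pi = true_aldvmm.mixture_weights(X)
    b = np.stack([(vs3.truncation_point - X @ true_aldvmm.betas[c])
                  / true_aldvmm.sigmas[c] for c in range(2)], axis=1)
    analytic = float((pi * norm.sf(b)).sum(axis=1).mean())
    emp = (y == 1).mean()
    se = np.sqrt(analytic * (1 - analytic) / len(y))
    assert abs(emp - analytic) < 3 * se + 1e-4


def test_extreme_params_all_full_health(vs3):
    p = ALDVMMParams(np.array([[50.0, 0.0, 0.0]]), np.array([0.01]),
                     np.zeros(0), vs3.floor, vs3.truncation_point,
                     converged=True)
    X = np.column_stack([np.ones(100), np.zeros((100, 2))])
    y = gen_eq5d_aldvmm(X, p, np.random.default_rng(0))
    assert np.all(y == 1.0)


def test_response_dgp_marginals_match_ordered_probit(vs3, true_suropm):
    df = gen_covariates(france_like_config(n=100_000, seed=5))
    X = _dgp_design(df, "response")
    levels, utils = gen_eq5d_response(X, true_suropm, vs3,
                                      np.random.default_rng(6))
    for d in range(5):
        kappa = np.concatenate([[-np.inf], true_suropm.cutpoints[d],
                                [np.inf]])
        xb = X @ true_suropm.thetas[d]
        for lev in (1, 2, 3):
            p_lev = float((norm.cdf(kappa[lev] - xb)
                           - norm.cdf(kappa[lev - 1] - xb)).mean())
            emp = (levels[:, d] == lev).mean()
            se = np.sqrt(p_lev * (1 - p_lev) / len(levels))
            assert abs(emp - p_lev) < 3 * se + 1e-4
    # utilities are tariff values of the emitted states
    assert np.all(utils <= 1.0) and np.all(utils >= vs3.floor)


def test_response_dgp_full_health_fraction(vs3, true_suropm):
    """Default truth puts roughly a quarter of respondents at full health."""
    df = gen_covariates(france_like_config(n=20_000, seed=7))
    X = _dgp_design(df, "response")
    levels, _ = gen_eq5d_response(X, true_suropm, vs3,
                                  np.random.default_rng(8))
    frac = (levels == 1).all(axis=1).mean()
    assert 0.21 <= frac <= 0.32


def test_extreme_cutpoints_single_level(vs3):
    p = default_true_suropm(3)
    p.cutpoints = [np.array([50.0, 100.0])] * 5
    df = gen_covariates(france_like_config(n=50, seed=1))
    X = _dgp_design(df, "response")
    levels, utils = gen_eq5d_response(X, p, vs3, np.random.default_rng(0))
    assert np.all(levels == 1) and np.all(utils == 1.0)


def test_gen_dataset_roundtrip_and_speed(tmp_path, vs3):
    t0 = time.perf_counter()
    df, sidecar = gen_dataset(SyntheticConfig(n=300, seed=12), vs3)
    assert time.perf_counter() - t0 < 5.0
    csv, js = tmp_path / "d.csv", tmp_path / "d.json"
    save_dataset(df, sidecar, csv, js)
    back = load_dataset(csv)
    for col in ("pcs", "kdcs", "eq5d_index"):
        assert np.array_equal(back[col].to_numpy(), df[col].to_numpy())
    assert sidecar["true_params"]["betas"]          # truth recorded


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(n=0)
    bad = np.eye(5)
    bad[0, 1] = bad[1, 0] = 1.2                     # not PD
    with pytest.raises(ValueError):
        SyntheticConfig(score_corr=bad)
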