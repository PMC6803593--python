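"""Cross-validation mechanics, metrics, ranking and correlation banding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import pearsonr, rankdata

from kdqolmap.evaluation import (CVMetrics, band, cross_validate, kfold_split,
                                 prediction_metrics, rank_models,
                                 spearman_rho)
from kdqolmap.models import fit_ols


def test_kfold_sizes():
    sizes = sorted(len(g) for g in kfold_split(163, 10, seed=1))
    assert sizes == [16] * 7 + [17] * 3
    assert all(len(g) == 30 for g in kfold_split(300, 10, seed=1))


def test_kfold_partition_and_determinism():
    folds = kfold_split(101, 10, seed=5)
    flat = np.concatenate(folds)
    assert sorted(flat.tolist()) == list(range(101))
    again = kfold_split(101, 10, seed=5)
    assert all(np.array_equal(a, b) for a, b in zip(folds, again))
    assert not all(np.array_equal(a, b)
                   for a, b in zip(folds, kfold_split(101, 10, seed=6)))


def test_kfold_rejects_small_n():
    with pytest.raises(ValueError):
        kfold_split(5, 10)


def test_metric_arithmetic():
    me, mae, rmse = prediction_metrics([1.0, 0.5], [0.9, 0.7])
    assert me == pytest.approx(0.05)
    assert mae == pytest.approx(0.15)
    assert rmse == pytest.approx(np.sqrt(0.025))
    assert prediction_metrics([0.3, 0.7], [0.3, 0.7]) == (0.0, 0.0, 0.0)


def test_cv_ols_approximates_residual_sd():
    rng = np.random.default_rng(0)
    n = 2000
    df = pd.DataFrame({"x": rng.normal(size=n)})
    y = 0.5 + 0.3 * df.x.to_numpy() + 0.2 * rng.normal(size=n)

    def fp(train, y_train, test):
        X = np.column_stack([np.ones(len(train)), train.x])
        fit = fit_ols(X, y_train)
        return fit.predict(np.column_stack([np.ones(len(test)), test.x]))

    m = cross_validate(fp, df, y, "ols", k=10, seed=1)
    assert m.converged
    assert m.rmse == pytest.approx(0.2, abs=0.02)
    assert abs(m.me) < 0.02


def test_cv_marks_failures_nonconverged():
    df = pd.DataFrame({"x": np.arange(20.0)})
    y = np.arange(20.0)

    def fp(train, y_train, test):
        raise RuntimeError("boom")

    m = cross_validate(fp, df, y, "bad", k=5, seed=0)
    assert not m.converged and np.isnan(m.mae)


def test_metric_invariant_enforced():
    with pytest.raises(ValueError, match="inconsistent"):
        CVMetrics("m", me=0.5, mae=0.1, rmse=0.2, n_predictions=10)


def test_rank_ties_resolved_by_rmse_then_id():
    ms = [CVMetrics("b", 0.0, 0.10, 0.20, 10),
          CVMetrics("a", 0.0, 0.10, 0.20, 10),
          CVMetrics("c", 0.0, 0.12, 0.15, 10)]
    # minimum ranking: identical metrics share ranks and rank sums
    tmin = rank_models(ms, ties="min").table.set_index("model_id")
    assert tmin.loc["b", "rank_sum"] == tmin.loc["a", "rank_sum"]
    # default ordinal ranking: order falls back to grid order, b before a
    t = rank_models(ms).table.set_index("model_id")
    assert t.loc["b", "final_rank"] < t.loc["a", "final_rank"]


def test_rank_excludes_nonconverged():
    ms = [CVMetrics("good", 0.0, 0.1, 0.2, 10),
          CVMetrics("bad", np.nan, np.nan, np.nan, 0, converged=False)]
    rk = rank_models(ms)
    assert rk.selected == "good"
    assert rk.excluded == ["bad"]
    with pytest.raises(ValueError):
        rank_models([ms[1]])


def test_min_tie_ranking_option():
    ms = [CVMetrics("a", 0.0, 0.10, 0.21, 10),
          CVMetrics("b", 0.0, 0.10, 0.20, 10)]
    t = rank_models(ms, ties="min").table.set_index("model_id")
    assert t.loc["a", "mae_rank"] == t.loc["b", "mae_rank"] == 1


def test_spearman_monotone_and_bands():
    x = np.arange(10.0)
    r = spearman_rho(x, np.exp(x))
    assert r.rho == pytest.approx(1.0)
    assert r.band == "very high"
    assert band(0.45) == "low"
    assert band(0.69) == "moderate"
    assert band(0.70) == "high"
    assert band(0.29) == "below-low"
    assert band(-0.75) == "high"            # banding uses |rho|


def test_spearman_matches_rank_then_pearson_oracle():
    rng = np.random.default_rng(9)
    for _ in range(20):
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.5 * x
        ours = spearman_rho(x, y).rho
        oracle = pearsonr(rankdata(x), rankdata(y)).statistic
        assert abs(ours - oracle) < 1e-12


def test_spearman_constant_input_flagged():
    with pytest.raises(ValueError, match="constant"):
        spearman_rho(np.ones(10), np.arange(10.0))


@given(st.lists(st.floats(-0.5, 1.0, allow_nan=False), min_size=3,
                max_size=40),
       st.lists(st.floats(-0.5, 1.0, allow_nan=False), min_size=3,
                max_size=40))
@settings(max_examples=50, deadline=None)
def test_metric_inequalities_hold(obs, pred):
    n = min(len(obs), len(pred))
    me, mae, rmse = prediction_metrics(obs[:n], pred[:n])
    assert rmse >= mae - 1e-12
    assert mae >= abs(me) - 1e-12
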