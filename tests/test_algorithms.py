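"""Grid enumeration, algorithm serialization/apply, correlation report."""

import numpy as np
import pandas as pd
import pytest

from kdqolmap.algorithms import (MappingAlgorithm, apply_algorithm, correlate,
                                 dataset_fingerprint, grid_entries)
from kdqolmap.design import DesignSpec, build_design, scale_features
from kdqolmap.models import fit_aldvmm, fit_ols


def test_grid_enumeration_counts():
    assert len(grid_entries()) == 36            # 6+6+6 + 6x3 ALDVMM
    assert len(grid_entries(components=(1, 2))) == 30
    ids = [e.model_id for e in grid_entries()]
    assert "ALD 6-2" in ids and "OPM 4" in ids and len(set(ids)) == 36
    ald62 = next(e for e in grid_entries() if e.model_id == "ALD 6-2")
    assert ald62.spec == DesignSpec("subscales", "sqint")
    assert ald62.components == 2


def _fit_ols_algo(df, vs3):
    spec = DesignSpec("subscales", "main")
    Xs, _ = scale_features(build_design(df, spec))
    fit = fit_ols(Xs.to_numpy(), df.eq5d_index.to_numpy(), list(Xs.columns))
    return MappingAlgorithm("ols", spec, fit, vs3,
                            provenance={"seed": 0})


def test_saved_ols_reproduces_predictions_bit_exact(tmp_path, vs3,
                                                    aldvmm_dataset):
    df, _ = aldvmm_dataset
    algo = _fit_ols_algo(df, vs3)
    before = algo.predict(df)
    path = tmp_path / "algo.json"
    algo.save(path)
    loaded = MappingAlgorithm.load(path)
    assert np.array_equal(loaded.predict(df), before)
    assert loaded.value_set.truncation_point == vs3.truncation_point


def test_saved_aldvmm_predicts_identically(tmp_path, vs3, aldvmm_dataset):
    df, _ = aldvmm_dataset
    spec = DesignSpec("summary", "main")
    Xs, _ = scale_features(build_design(df, spec))
    fit = fit_aldvmm(Xs.to_numpy(), df.eq5d_index.to_numpy(), vs3, 2,
                     n_starts=4, seed=0, feature_names=list(Xs.columns))
    algo = MappingAlgorithm("aldvmm", spec, fit, vs3)
    path = tmp_path / "a.json"
    algo.save(path)
    loaded = MappingAlgorithm.load(path)
    rng = np.random.default_rng(3)
    new = pd.DataFrame({
        "pcs": rng.uniform(0, 100, 1000), "mcs": rng.uniform(0, 100, 1000),
        "symptoms": rng.uniform(0, 100, 1000),
        "effects": rng.uniform(0, 100, 1000),
        "burden": rng.uniform(0, 100, 1000),
        "age": rng.uniform(18, 95, 1000),
        "sex": np.where(rng.random(1000) < 0.5, "male", "female")})
    new["kdcs"] = (new.symptoms + new.effects + new.burden) / 3
    assert np.array_equal(algo.predict(new), loaded.predict(new))


def test_apply_algorithm_row_level_errors(vs3, aldvmm_dataset):
    df, _ = aldvmm_dataset
    algo = _fit_ols_algo(df, vs3)
    newdf = df.head(5).copy().reset_index(drop=True)
    newdf.loc[2, "burden"] = np.nan
    out = apply_algorithm(algo, newdf)
    assert out.loc[2, "error"].startswith("missing: burden")
    assert np.isnan(out.loc[2, "prediction"])
    assert out.loc[[0, 1, 3, 4], "prediction"].notna().all()
    with pytest.raises(ValueError, match="missing required columns"):
        apply_algorithm(algo, newdf.drop(columns=["burden"]))


def test_correlation_report_structure(response_dataset):
    df, _ = response_dataset
    rep = correlate(df)
    b1 = rep[rep.block == "score_x_outcome"]
    assert len(b1) == 6 * 6                     # 6 scores x (index + 5 items)
    pairs = {frozenset((r.var1, r.var2))
             for r in rep[rep.block == "score_x_score"].itertuples()}
    for comp in ("symptoms", "effects", "burden"):
        assert frozenset(("kdcs", comp)) not in pairs
    assert len(pairs) == 12                     # C(6,2)=15 minus 3 structural
    assert len(rep[rep.block == "item_x_item"]) == 10
    assert rep.loc[rep.note == "", "rho"].abs().le(1).all()


def test_correlation_constant_column_flagged(aldvmm_dataset):
    df, _ = aldvmm_dataset
    df = df.copy()
    df["pcs"] = 50.0
    rep = correlate(df)
    flagged = rep[(rep.var1 == "pcs") & (rep.note != "")]
    assert len(flagged) > 0


def test_dataset_fingerprint_sensitivity(aldvmm_dataset):
    df, _ = aldvmm_dataset
    f1 = dataset_fingerprint(df)
    df2 = df.copy()
    df2.loc[0, "pcs"] += 1e-9
    assert f1 == dataset_fingerprint(df)
    assert f1 != dataset_fingerprint(df2)
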