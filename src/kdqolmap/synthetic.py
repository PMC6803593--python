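"""Synthetic respondent data with the statistical structure of dialysis
surveys.

The generator emulates the features the estimators are built for: bounded,
left-skewed KDQOL-36 subscale scores with realistic means/SDs and moderate
positive inter-score correlations; and EQ-5D utilities that are multimodal,
spiked at full health (roughly a fifth to a third of respondents), empty on
the gap (Ψ, 1), and floored at the worst-state value.

Two outcome DGPs are provided, deliberately model-matched to the two
estimator families so that parameter recovery is a fair oracle:

* ``aldvmm_dgp`` — draw a mixture component, draw the latent normal, censor
  at Ψ (observed as 1) and at the floor;
* ``response_dgp`` — draw correlated MVN latents, threshold each into an item
  level, value the resulting health state with the tariff.

Every run is reproducible from the seed; a sidecar dict records every true
parameter for recovery tests.  Covariate defaults follow a French dialysis
sample (PCS 39.90 (10.09), MCS 46.51 (9.61), Symptoms 78.48 (20.18), Effects
70.55 (24.45), Burden 48.20 (28.82), age 66.6 (14.1), 62.5% male).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kdqol import compute_kdcs, SCORE_COLUMNS
from .models.aldvmm import ALDVMMParams
from .models.suropm import SUROPMParams
from .valuesets import ValueSet, toy_3l

__all__ = ["SyntheticConfig", "gen_covariates", "gen_eq5d_aldvmm",
           "gen_eq5d_response", "gen_dataset", "france_like_config"]

# France-like sample moments: scores as mean (SD)
_DEFAULT_MEANS = {"pcs": 39.90, "mcs": 46.51, "symptoms": 78.48,
                  "effects": 70.55, "burden": 48.20}
_DEFAULT_SDS = {"pcs": 10.09, "mcs": 9.61, "symptoms": 20.18,
                "effects": 24.45, "burden": 28.82}
# moderate positive correlations (no pair high), order as SCORE_COLUMNS
_DEFAULT_CORR = np.array([
    [1.00, 0.30, 0.45, 0.45, 0.40],
    [0.30, 1.00, 0.40, 0.45, 0.40],
    [0.45, 0.40, 1.00, 0.60, 0.50],
    [0.45, 0.45, 0.60, 1.00, 0.55],
    [0.40, 0.40, 0.50, 0.55, 1.00],
])


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate a French dialysis sample."""

    n: int = 299
    seed: int = 0
    score_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    score_sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    score_corr: np.ndarray = field(default_factory=lambda: _DEFAULT_CORR.copy())
    age_mean: float = 66.6
    age_sd: float = 14.1
    age_min: float = 18.0
    male_prop: float = 0.625
    outcome_dgp: str = "aldvmm_dgp"   # or "response_dgp"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        corr = np.asarray(self.score_corr, dtype=float)
        if corr.shape != (5, 5) or not np.allclose(corr, corr.T):
            raise ValueError("score_corr must be a symmetric 5x5 matrix")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("score_corr must be positive definite")
        self.score_corr = corr


def france_like_config(n: int = 299, seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(n=n, seed=seed)


def gen_covariates(config: SyntheticConfig) -> pd.DataFrame:
    """Scores (clipped latent MVN), derived KDCS, age (truncated), sex.

    The clip rate is recorded in ``df.attrs['clip_rate']`` so tests can bound
    the moment distortion it introduces.
    """
    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(config.score_corr)
    z = rng.standard_normal((config.n, 5)) @ chol.T
    means = np.array([config.score_means[c] for c in SCORE_COLUMNS])
    sds = np.array([config.score_sds[c] for c in SCORE_COLUMNS])
    raw = means + z * sds
    clipped = np.clip(raw, 0.0, 100.0)
    clip_rate = float((raw != clipped).mean())
    df = pd.DataFrame(clipped, columns=list(SCORE_COLUMNS))
    df["kdcs"] = compute_kdcs(df["symptoms"].to_numpy(),
                              df["effects"].to_numpy(),
                              df["burden"].to_numpy())
    age = config.age_mean + config.age_sd * rng.standard_normal(config.n)
    while (age < config.age_min).any():  # redraw below the truncation age
        m = age < config.age_min
        age[m] = config.age_mean + config.age_sd * rng.standard_normal(m.sum())
    df["age"] = age
    df["sex"] = np.where(rng.random(config.n) < config.male_prop,
                         "male", "female")
    df.attrs["clip_rate"] = clip_rate
    return df


def gen_eq5d_aldvmm(covariate_design: np.ndarray, true_params: ALDVMMParams,
                    rng) -> np.ndarray:
    """Utilities from the adjusted-normal mixture observation model.

    Latents at or above Ψ are observed as 1, at or below the floor as the
    floor; nothing lands in the gap (Ψ, 1).
    """
    X = np.asarray(covariate_design, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pi = true_params.mixture_weights(X)
    comp = np.array([rng.choice(true_params.n_components, p=row)
                     for row in pi]) if true_params.n_components > 1 \
        else np.zeros(n, dtype=int)
    mu = np.einsum("ij,ij->i", X, true_params.betas[comp])
    latent = mu + true_params.sigmas[comp] * rng.standard_normal(n)
    y = np.where(latent >= true_params.psi, 1.0,
                 np.where(latent <= true_params.y_min, true_params.y_min,
                          latent))
    return y


def gen_eq5d_response(covariate_design: np.ndarray,
                      true_params: SUROPMParams, vs: ValueSet,
                      rng) -> tuple[np.ndarray, np.ndarray]:
    """Item-level responses and their tariff utilities from the joint
    ordered-probit model."""
    X = np.asarray(covariate_design, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    chol = np.linalg.cholesky(true_params.corr)
    eps = rng.standard_normal((n, 5)) @ chol.T
    latent = X @ true_params.thetas.T + eps
    levels = np.empty((n, 5), dtype=int)
    for d in range(5):
        levels[:, d] = 1 + np.searchsorted(true_params.cutpoints[d],
                                           latent[:, d], side="left")
    utils = np.array([vs.index_of_levels(lv) for lv in levels])
    return levels, utils


def default_true_aldvmm(value_set: ValueSet | None = None) -> ALDVMMParams:
    """A two-component truth on [const, kdcs/100, age/10] producing a
    full-health spike near 20% and a France-like mean utility."""
    vs = value_set or toy_3l()
    betas = np.array([
        [0.90, 0.45, -0.05],    # healthier cluster, pushed into the ceiling
        [0.35, 0.55, -0.03],    # sicker cluster, continuous body
    ])
    return ALDVMMParams(betas=betas, sigmas=np.array([0.20, 0.28]),
                        delta=np.array([-0.75]), y_min=vs.floor,
                        psi=vs.truncation_point,
                        feature_names=["const", "kdcs_s", "age_s"],
                        converged=True)


def default_true_suropm(n_levels: int = 3) -> SUROPMParams:
    """A joint ordered-probit truth on [kdcs/100, age/10] with moderate
    positive correlations between item errors."""
    p = 2
    thetas = np.array([[-1.8, 0.10], [-1.5, 0.05], [-2.0, 0.12],
                       [-2.2, 0.08], [-1.2, 0.04]])
    # cutpoints sit ~0.3 latent-SD above the mean index, putting ~26% of a
    # France-like sample at full health with every level well-populated
    if n_levels == 3:
        cutpoints = [np.array([-0.20, 1.10]), np.array([-0.35, 0.95]),
                     np.array([-0.20, 1.10]), np.array([-0.60, 0.70]),
                     np.array([-0.20, 1.10])]
    else:
        offs = (-0.20, -0.35, -0.20, -0.60, -0.20)
        cutpoints = [o + np.array([0.0, 0.7, 1.4, 2.1]) for o in offs]
    corr = 0.45 * np.ones((5, 5))
    np.fill_diagonal(corr, 1.0)
    return SUROPMParams(thetas, cutpoints, corr, n_levels,
                        feature_names=["kdcs_s", "age_s"], converged=True)


def _dgp_design(df: pd.DataFrame, kind: str) -> np.ndarray:
    kdcs_s = df["kdcs"].to_numpy() / 100.0
    age_s = df["age"].to_numpy() / 10.0
    if kind == "aldvmm":
        return np.column_stack([np.ones(len(df)), kdcs_s, age_s])
    return np.column_stack([kdcs_s, age_s])


def gen_dataset(config: SyntheticConfig, value_set: ValueSet | None = None,
                true_aldvmm: ALDVMMParams | None = None,
                true_suropm: SUROPMParams | None = None
                ) -> tuple[pd.DataFrame, dict]:
    """Complete CSV-ready dataset plus a sidecar of every true parameter."""
    vs = value_set or toy_3l()
    df = gen_covariates(config)
    rng = np.random.default_rng(config.seed + 1)
    sidecar = {"config": {"n": config.n, "seed": config.seed,
                          "outcome_dgp": config.outcome_dgp},
               "value_set": vs.to_dict(),
               "clip_rate": df.attrs["clip_rate"]}
    if config.outcome_dgp == "aldvmm_dgp":
        truth = true_aldvmm or default_true_aldvmm(vs)
        y = gen_eq5d_aldvmm(_dgp_design(df, "aldvmm"), truth, rng)
        df["eq5d_index"] = y
        sidecar["true_params"] = truth.to_dict()
    elif config.outcome_dgp == "response_dgp":
        truth = true_suropm or default_true_suropm(
            3 if vs.version == "3L" else 5)
        levels, utils = gen_eq5d_response(_dgp_design(df, "response"),
                                          truth, vs, rng)
        for j, col in enumerate(("mo", "sc", "ua", "pd", "ad")):
            df[col] = levels[:, j]
        df["eq5d_index"] = utils
        sidecar["true_params"] = truth.to_dict()
    else:
        raise ValueError(f"unknown outcome_dgp {config.outcome_dgp!r}")
    df.insert(0, "id", np.arange(1, len(df) + 1))
    return df, sidecar


def save_dataset(df: pd.DataFrame, sidecar: dict, csv_path, json_path) -> None:
    df.to_csv(csv_path, index=False)
    Path(json_path).write_text(json.dumps(sidecar, indent=1))
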