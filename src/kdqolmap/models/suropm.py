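"""Seemingly unrelated ordered probit response mapping (SUROPM).

Each of the five EQ-5D items d gets an ordered-probit equation: the observed
level is l when κ_{d,l−1} < x·θ_d + ε_d ≤ κ_{d,l} with strictly increasing
cutpoints (κ_{d,0} = −∞, κ_{d,L} = +∞).  The five latent errors are jointly
multivariate normal with a free correlation matrix R (unit diagonal), so the
likelihood of a response vector is an orthant probability evaluated by the
GHK simulator (:mod:`.ghk`).  Expected utility is the value-set-weighted
average over all L⁵ health states: Σ_s P(s|x)·U(s).  Unlike the direct
models, the expectation is a convex combination of tariff values and can
legitimately fall inside the gap (Ψ, 1).

Estimation is staged: (1) five independent ordered probits (consistent for
θ, κ because the marginals of a MVN probit are univariate probits) give the
warm start; (2) R is estimated by maximum simulated likelihood with θ, κ
fixed; (3) optionally all parameters are refined jointly
(``refine="joint"``).  R is parameterised through row-normalised Cholesky
factors, so it is positive definite with unit diagonal at every iterate, and
cutpoints through log-increments, so monotonicity always holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .ghk import ghk_draws, ghk_probs
from ..valuesets import ValueSet

__all__ = ["SUROPMParams", "suropm_loglik", "fit_suropm",
           "predict_state_probs", "predict_utility_response"]

_NDIM = 5


@dataclass
class SUROPMParams:
    """Joint ordered-probit parameters for the five EQ-5D items.

    ``thetas``: (5, p) slope vectors (no intercept; cutpoints absorb it).
    ``cutpoints``: five strictly increasing arrays (length L_d − 1).
    ``corr``: 5×5 latent-error correlation matrix.
    ``level_values``: per item, the original level code each fitted category
    represents (identity unless sparse levels were merged).
    """

    thetas: np.ndarray
    cutpoints: list
    corr: np.ndarray
    n_levels: int
    level_values: list = None
    feature_names: list | None = None
    ghk_n_draws: int = 200
    ghk_seed: int = 0
    loglik: float = np.nan
    n: int = 0
    converged: bool = False

    def __post_init__(self):
        if self.level_values is None:
            self.level_values = [list(range(1, len(k) + 2))
                                 for k in self.cutpoints]

    def to_dict(self) -> dict:
        return {"thetas": np.asarray(self.thetas).tolist(),
                "cutpoints": [np.asarray(k).tolist() for k in self.cutpoints],
                "correlation_matrix": np.asarray(self.corr).tolist(),
                "n_levels": self.n_levels,
                "level_values": self.level_values,
                "feature_names": self.feature_names,
                "ghk": {"draws": self.ghk_n_draws, "seed": self.ghk_seed},
                "loglik": self.loglik, "n": self.n, "converged": self.converged}

    @classmethod
    def from_dict(cls, d) -> "SUROPMParams":
        return cls(np.asarray(d["thetas"], float),
                   [np.asarray(k, float) for k in d["cutpoints"]],
                   np.asarray(d["correlation_matrix"], float),
                   int(d["n_levels"]), d.get("level_values"),
                   d.get("feature_names"), int(d["ghk"]["draws"]),
                   int(d["ghk"]["seed"]), float(d["loglik"]), int(d["n"]),
                   bool(d["converged"]))


# -- correlation parameterisation ---------------------------------------------

def _tril_index_pairs(d=_NDIM):
    return [(i, j) for i in range(1, d) for j in range(i)]


def _z_to_chol(z, d=_NDIM):
    """Unconstrained strictly-lower-triangular entries -> row-normalised
    Cholesky factor; R = LLᵀ is PD with unit diagonal for any z."""
    L = np.eye(d)
    for (i, j), v in zip(_tril_index_pairs(d), z):
        L[i, j] = v
    return L / np.linalg.norm(L, axis=1, keepdims=True)


def _chol_to_z(L, d=_NDIM):
    return np.array([L[i, j] / L[i, i] for i, j in _tril_index_pairs(d)])


# -- likelihood ---------------------------------------------------------------

def _drop_const(X, feature_names):
    """Drop intercept columns (all ones): the cutpoints absorb location."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    const_cols = [j for j in range(X.shape[1]) if np.all(X[:, j] == 1.0)]
    if const_cols:
        keep = [j for j in range(X.shape[1]) if j not in const_cols]
        X = X[:, keep]
        if feature_names is not None:
            feature_names = [feature_names[j] for j in keep]
    return X, feature_names


def _bounds_for_responses(thetas, cutpoints, X, responses):
    """Latent-error bounds (lower, upper), each (n, 5)."""
    n = X.shape[0]
    lower = np.empty((n, _NDIM))
    upper = np.empty((n, _NDIM))
    for d in range(_NDIM):
        kappa = np.concatenate([[-np.inf], cutpoints[d], [np.inf]])
        lev = responses[:, d]
        xb = X @ thetas[d]
        lower[:, d] = kappa[lev - 1] - xb
        upper[:, d] = kappa[lev] - xb
    return lower, upper


def _responses_to_categories(responses, level_values):
    """Map original level codes to fitted category indices 1..K_d."""
    out = np.empty_like(responses)
    for d in range(_NDIM):
        lut = {lv: i + 1 for i, lv in enumerate(level_values[d])}
        try:
            out[:, d] = [lut[v] for v in responses[:, d]]
        except KeyError as e:
            raise ValueError(f"item {d}: unseen level {e.args[0]}") from None
    return out


def suropm_loglik(params: SUROPMParams, X, responses) -> float:
    """Simulated log-likelihood of the observed level vectors."""
    X, _ = _drop_const(X, None)
    responses = np.asarray(responses, dtype=int)
    cat = _responses_to_categories(responses, params.level_values)
    lower, upper = _bounds_for_responses(params.thetas, params.cutpoints,
                                         X, cat)
    u = ghk_draws(params.ghk_n_draws, _NDIM, params.ghk_seed)
    chol = np.linalg.cholesky(params.corr)
    p = ghk_probs(lower, upper, chol, u)
    return float(np.log(np.clip(p, 1e-300, None)).sum())


# -- fitting ------------------------------------------------------------------

def _fit_marginal_probits(X, cat, feature_names):
    """Five independent ordered probits (statsmodels), consistent warm start."""
    thetas, cutpoints, ll = [], [], 0.0
    for d in range(_NDIM):
        endog = cat[:, d] - 1
        K = endog.max() + 1
        model = OrderedModel(pd.Series(endog).astype(
            pd.CategoricalDtype(categories=range(K), ordered=True)),
            X, distr="probit")
        res = model.fit(method="bfgs", disp=0, maxiter=500)
        p = X.shape[1]
        # statsmodels latent: P(y<=j) = F(kappa_j - x beta): same convention
        thetas.append(res.params[:p])
        thresh = model.transform_threshold_params(res.params)
        cutpoints.append(np.asarray(thresh[1:-1]))
        ll += res.llf
    return np.asarray(thetas), cutpoints, float(ll)


def _pack_joint(thetas, cutpoints, z):
    parts = [np.ravel(thetas)]
    for k in cutpoints:
        parts.append(np.concatenate([[k[0]], np.log(np.diff(k))])
                     if len(k) > 1 else np.asarray(k))
    parts.append(z)
    return np.concatenate(parts)


def _unpack_joint(theta, p, k_sizes):
    npar = _NDIM * p
    thetas = theta[:npar].reshape(_NDIM, p)
    cutpoints = []
    pos = npar
    for ks in k_sizes:
        raw = theta[pos:pos + ks]
        pos += ks
        if ks > 1:
            cutpoints.append(np.concatenate([[raw[0]],
                                             raw[0] + np.cumsum(np.exp(raw[1:]))]))
        else:
            cutpoints.append(np.asarray(raw))
    z = theta[pos:]
    return thetas, cutpoints, z


def fit_suropm(X, responses, n_levels: int, *, n_draws: int = 200,
               ghk_seed: int = 0, refine: str = "joint",
               joint_maxiter: int = 40, merge_levels: dict | None = None,
               feature_names=None) -> SUROPMParams:
    """Maximum simulated likelihood fit of the joint ordered-probit system.

    ``merge_levels`` maps an item index (0-based) to ``{from: to}`` level
    collapses for sparse categories (e.g. ``{3: {5: 4}}`` merges 'extreme'
    into 'severe' on pain/discomfort); by default an unobserved level is a
    hard error.  ``refine="none"`` stops after the correlation stage, which
    is consistent and far cheaper — grid cross-validation uses it.
    """
    if refine not in ("joint", "none"):
        raise ValueError("refine must be 'joint' or 'none'")
    X, feature_names = _drop_const(X, feature_names)
    responses = np.asarray(responses, dtype=int)
    if responses.shape[1] != _NDIM:
        raise ValueError("responses must have five columns")
    # level handling
    level_values = []
    work = responses.copy()
    for d in range(_NDIM):
        remap = (merge_levels or {}).get(d, {})
        col = np.array([remap.get(v, v) for v in responses[:, d]])
        observed = sorted(set(col))
        expected = [lv for lv in range(1, n_levels + 1)
                    if remap.get(lv, lv) == lv]
        missing = sorted(set(expected) - set(observed))
        if missing:
            raise ValueError(
                f"item {d}: level(s) {missing} never observed; response "
                "mapping needs observations at every level of every item — "
                "consider merging sparse adjacent levels via merge_levels")
        work[:, d] = col
        level_values.append(observed)
    cat = _responses_to_categories(work, level_values)
    n, p = X.shape
    thetas, cutpoints, _ = _fit_marginal_probits(X, cat, feature_names)
    u = ghk_draws(n_draws, _NDIM, ghk_seed)

    def nll_corr(z):
        chol = _z_to_chol(z)
        lower, upper = _bounds_for_responses(thetas, cutpoints, X, cat)
        pr = ghk_probs(lower, upper, chol, u)
        return -float(np.log(np.clip(pr, 1e-300, None)).sum())

    res_r = optimize.minimize(nll_corr, np.zeros(len(_tril_index_pairs())),
                              method="L-BFGS-B",
                              options={"maxiter": 100, "ftol": 1e-9})
    z = res_r.x
    converged = bool(res_r.success)
    loglik = -float(res_r.fun)
    if refine == "joint":
        k_sizes = [len(k) for k in cutpoints]

        def nll_joint(t):
            th, cp, zz = _unpack_joint(t, p, k_sizes)
            lower, upper = _bounds_for_responses(th, cp, X, cat)
            pr = ghk_probs(lower, upper, _z_to_chol(zz), u)
            return -float(np.log(np.clip(pr, 1e-300, None)).sum())

        t0 = _pack_joint(thetas, cutpoints, z)
        res_j = optimize.minimize(nll_joint, t0, method="L-BFGS-B",
                                  options={"maxiter": joint_maxiter,
                                           "ftol": 1e-9})
        if np.isfinite(res_j.fun) and res_j.fun <= res_r.fun:
            thetas, cutpoints, z = _unpack_joint(res_j.x, p, k_sizes)
            loglik = -float(res_j.fun)
            converged = converged or bool(res_j.success)
    chol = _z_to_chol(z)
    corr = chol @ chol.T
    np.fill_diagonal(corr, 1.0)
    return SUROPMParams(thetas, cutpoints, corr, n_levels, level_values,
                        feature_names, n_draws, ghk_seed, loglik, n,
                        converged)


# -- prediction ---------------------------------------------------------------

def _fitted_states(params: SUROPMParams):
    """All category combinations (fitted space) and the original level codes
    they represent."""
    from itertools import product
    cats = [range(1, len(k) + 2) for k in params.cutpoints]
    combos = np.array(list(product(*cats)), dtype=int)
    orig = np.empty_like(combos)
    for d in range(_NDIM):
        lut = np.asarray(params.level_values[d])
        orig[:, d] = lut[combos[:, d] - 1]
    return combos, orig


def predict_state_probs(params: SUROPMParams, X,
                        chunk: int = 200_000) -> np.ndarray:
    """P(state | x) over all fitted health states, enumeration order.

    Returns (n, n_states); probabilities are clipped at 0 and renormalised to
    sum to exactly 1 (the raw GHK estimates sum to 1 only within simulation
    noise).
    """
    X, _ = _drop_const(X, None)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    combos, _ = _fitted_states(params)
    n_states = combos.shape[0]
    u = ghk_draws(params.ghk_n_draws, _NDIM, params.ghk_seed)
    chol = np.linalg.cholesky(params.corr)
    xb = X @ params.thetas.T  # (n, 5)
    kappas = [np.concatenate([[-np.inf], k, [np.inf]])
              for k in params.cutpoints]
    out = np.empty((n, n_states))
    rows_per_chunk = max(1, chunk // max(n_states, 1))
    for start in range(0, n, rows_per_chunk):
        stop = min(start + rows_per_chunk, n)
        nb = stop - start
        lower = np.empty((nb, n_states, _NDIM))
        upper = np.empty((nb, n_states, _NDIM))
        for d in range(_NDIM):
            lo = kappas[d][combos[:, d] - 1]
            hi = kappas[d][combos[:, d]]
            lower[:, :, d] = lo[None, :] - xb[start:stop, d][:, None]
            upper[:, :, d] = hi[None, :] - xb[start:stop, d][:, None]
        pr = ghk_probs(lower.reshape(-1, _NDIM), upper.reshape(-1, _NDIM),
                       chol, u).reshape(nb, n_states)
        out[start:stop] = pr
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=1, keepdims=True)
    return out


def predict_utility_response(params: SUROPMParams, X, vs) -> np.ndarray:
    """Expected utility Σ_s P(s|x)·U(s).

    ``vs`` may be a single :class:`ValueSet` or a sequence of per-record
    value sets (pooled estimation with country-specific valuation).
    """
    X, _ = _drop_const(X, None)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    probs = predict_state_probs(params, X)
    _, orig = _fitted_states(params)
    version = "3L" if params.n_levels == 3 else "5L"
    vsets = [vs] * n if isinstance(vs, ValueSet) else list(vs)
    if len(vsets) != n:
        raise ValueError("need one value set per record")
    cache: dict[str, np.ndarray] = {}
    out = np.empty(n)
    for i, v in enumerate(vsets):
        if v.version != version:
            raise ValueError(f"value set version {v.version} != model {version}")
        if v.name not in cache:
            cache[v.name] = np.array([v.index_of_levels(lv) for lv in orig])
        out[i] = probs[i] @ cache[v.name]
    return out
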