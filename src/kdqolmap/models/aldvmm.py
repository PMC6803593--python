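"""Adjusted limited dependent variable mixture model (ALDVMM).

The observable EQ-5D utility lives on {1} ∪ [y_min, Ψ]: a probability spike at
full health, a gap (Ψ, 1) that no tariff value occupies, a continuous body and
a floor at the worst-state value y_min.  The ALDVMM models the utility as a
C-component mixture of *adjusted* normals: within component c with mean
μ_c = xβ_c and scale σ_c, a latent normal at or above Ψ is observed as 1, at
or below y_min as y_min, and in between as itself.  With a_c = (y_min−μ_c)/σ_c
and b_c = (Ψ−μ_c)/σ_c the per-record density/mass is

    f_c(y|x) = 1{y=1}·(1−Φ(b_c)) + 1{y=y_min}·Φ(a_c)
             + 1{y_min<y≤Ψ}·φ((y−μ_c)/σ_c)/σ_c

and the likelihood is Σ_c π_c f_c.  Observations exactly at Ψ are treated as
continuous-part realisations; the point masses sit only at 1 and y_min.

Component-membership probabilities are covariate-free constant logits by
default (``membership="constant"``), with covariate-dependent logits
available.  Estimation is maximum likelihood with analytic gradients,
quasi-Newton, and OLS-anchored multi-starts; a fit whose optimizer never
converges is returned flagged ``converged=False`` rather than raising, so a
model grid can exclude it from ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy.stats import norm

from .ols import fit_ols

__all__ = ["ALDVMMParams", "aldvmm_loglik", "fit_aldvmm", "predict_aldvmm"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ALDVMMParams:
    """Fitted (or hypothesised) ALDVMM parameters.

    ``betas`` has shape (C, p); ``sigmas`` shape (C,); ``delta`` holds the
    membership logits — shape (C-1,) for constant membership or (C-1, p) for
    covariate-dependent — with the last component's logit fixed at 0.
    """

    betas: np.ndarray
    sigmas: np.ndarray
    delta: np.ndarray
    y_min: float
    psi: float
    feature_names: list[str] | None = None
    membership: str = "constant"
    loglik: float = np.nan
    n: int = 0
    converged: bool = False

    @property
    def n_components(self) -> int:
        return self.betas.shape[0]

    def mixture_weights(self, X) -> np.ndarray:
        """π(x), shape (n, C)."""
        C = self.n_components
        n = np.asarray(X).shape[0]
        if C == 1:
            return np.ones((n, 1))
        if self.membership == "constant":
            logits = np.concatenate([np.ravel(self.delta), [0.0]])
            logits = np.broadcast_to(logits, (n, C))
        else:
            eta = np.asarray(X, dtype=float) @ np.asarray(self.delta).T
            logits = np.column_stack([eta, np.zeros(n)])
        return special.softmax(logits, axis=1)

    def to_dict(self) -> dict:
        return {"betas": self.betas.tolist(), "sigmas": self.sigmas.tolist(),
                "delta": np.asarray(self.delta).tolist(),
                "y_min": self.y_min, "psi": self.psi,
                "feature_names": self.feature_names,
                "membership": self.membership, "loglik": self.loglik,
                "n": self.n, "converged": self.converged}

    @classmethod
    def from_dict(cls, d) -> "ALDVMMParams":
        return cls(np.asarray(d["betas"], float), np.asarray(d["sigmas"], float),
                   np.asarray(d["delta"], float), float(d["y_min"]),
                   float(d["psi"]), d.get("feature_names"),
                   d.get("membership", "constant"), float(d["loglik"]),
                   int(d["n"]), bool(d["converged"]))


def _check_support(y: np.ndarray, y_min: float, psi: float, tol: float = 1e-9):
    y = np.asarray(y, dtype=float)
    if psi < 1.0:   # degenerate bounds (psi >= 1) leave no gap to police
        in_gap = (y > psi + tol) & (y < 1.0 - tol)
        if in_gap.any():
            raise ValueError(
                f"{int(in_gap.sum())} outcomes fall in the infeasible gap "
                f"({psi}, 1); utilities must lie in {{1}} ∪ [{y_min}, {psi}]")
    if (y > max(psi, 1.0) + tol).any() or (y < y_min - tol).any():
        raise ValueError("outcomes outside the feasible range")
    return y


def _case_masks(y, y_min, psi, tol=1e-9):
    at_one = np.abs(y - 1.0) <= tol
    at_floor = np.abs(y - y_min) <= tol
    interior = ~at_one & ~at_floor
    return at_one, at_floor, interior


def _component_logf(y, mu, sigma, y_min, psi, masks):
    """log f_c and d log f_c / dμ, / dlogσ for one component (vectorized in n)."""
    at_one, at_floor, interior = masks
    a = (y_min - mu) / sigma
    b = (psi - mu) / sigma
    logf = np.empty_like(mu)
    dmu = np.empty_like(mu)
    dls = np.empty_like(mu)
    # ceiling: 1 - Φ(b)
    if at_one.any():
        bb = b[at_one]
        logsf = norm.logsf(bb)
        logf[at_one] = logsf
        # hazard capped: where the mass is ~0 the responsibility weight is 0
        haz = np.exp(np.minimum(norm.logpdf(bb) - logsf, 300.0))
        dmu[at_one] = haz / sigma
        dls[at_one] = haz * bb
    # floor: Φ(a)
    if at_floor.any():
        aa = a[at_floor]
        logcdf = norm.logcdf(aa)
        logf[at_floor] = logcdf
        rev = np.exp(np.minimum(norm.logpdf(aa) - logcdf, 300.0))
        dmu[at_floor] = -rev / sigma
        dls[at_floor] = -rev * aa
    # interior: φ(u)/σ
    if interior.any():
        u = (y[interior] - mu[interior]) / sigma
        logf[interior] = -0.5 * (_LOG2PI + u ** 2) - np.log(sigma)
        dmu[interior] = u / sigma
        dls[interior] = u ** 2 - 1.0
    return logf, dmu, dls


def _unpack(theta, C, p, membership):
    nb = C * p
    betas = theta[:nb].reshape(C, p)
    logsig = theta[nb:nb + C]
    q = 0 if C == 1 else (C - 1) * (p if membership == "covariate" else 1)
    delta = theta[nb + C: nb + C + q]
    if membership == "covariate":
        delta = delta.reshape(C - 1, p) if C > 1 else delta.reshape(0, p)
    return betas, logsig, delta


def _negloglik_and_grad(theta, X, y, y_min, psi, C, membership, masks):
    n, p = X.shape
    betas, logsig, delta = _unpack(theta, C, p, membership)
    sigmas = np.exp(logsig)
    # membership logits per record
    if C == 1:
        logpi = np.zeros((n, 1))
    elif membership == "constant":
        logits = np.concatenate([np.ravel(delta), [0.0]])
        logpi = np.broadcast_to(special.log_softmax(logits), (n, C))
    else:
        eta = np.column_stack([X @ delta.T, np.zeros(n)])
        logpi = special.log_softmax(eta, axis=1)
    logf = np.empty((n, C))
    dmu = np.empty((n, C))
    dls = np.empty((n, C))
    for c in range(C):
        logf[:, c], dmu[:, c], dls[:, c] = _component_logf(
            y, X @ betas[c], sigmas[c], y_min, psi, masks)
    logmix = logpi + logf
    ll_i = special.logsumexp(logmix, axis=1)
    nll = -float(ll_i.sum())
    w = np.exp(logmix - ll_i[:, None])  # responsibilities π_c f_c / L
    grad = np.empty_like(theta)
    gb = (w * dmu).T @ X                      # (C, p)
    grad[:C * p] = -gb.ravel()
    grad[C * p:C * p + C] = -(w * dls).sum(axis=0)
    if C > 1:
        resid = w - np.exp(logpi)             # ∂ll_i/∂η_ic
        if membership == "constant":
            grad[C * p + C:] = -resid[:, :-1].sum(axis=0)
        else:
            grad[C * p + C:] = -(resid[:, :-1].T @ X).ravel()
    if not (np.isfinite(nll) and np.all(np.isfinite(grad))):
        nll = 1e12
        grad = np.zeros_like(grad)
    return nll, grad


def aldvmm_loglik(params: ALDVMMParams, X, y) -> float:
    """Log-likelihood of the data under ``params`` (support-checked)."""
    X = np.asarray(X, dtype=float)
    y = _check_support(y, params.y_min, params.psi)
    masks = _case_masks(y, params.y_min, params.psi)
    n, p = X.shape
    C = params.n_components
    theta = _pack(params)
    nll, _ = _negloglik_and_grad(theta, X, y, params.y_min, params.psi, C,
                                 params.membership, masks)
    return -nll


def _pack(params: ALDVMMParams) -> np.ndarray:
    parts = [params.betas.ravel(), np.log(params.sigmas)]
    if params.n_components > 1:
        parts.append(np.ravel(params.delta))
    return np.concatenate(parts)


def _starts(X, y, y_min, psi, C, membership, n_starts, rng, feature_names):
    """OLS-anchored starts plus random perturbations."""
    p = X.shape[1]
    try:
        ols = fit_ols(X, y, feature_names)
        beta0, s0 = ols.coefficients, max(ols.residual_sd, 0.05)
    except Exception:
        beta0 = np.zeros(p)
        beta0[0] = np.mean(y)
        s0 = max(np.std(y), 0.05)
    q = 0 if C == 1 else (C - 1) * (p if membership == "covariate" else 1)
    starts = []
    # anchored start: OLS slopes, intercepts spread over the outcome range
    spread = np.linspace(-1.0, 1.0, C) * (np.std(y) + 1e-3)
    base = np.tile(beta0, (C, 1))
    base[:, 0] += spread
    starts.append(np.concatenate([base.ravel(), np.full(C, np.log(s0)),
                                  np.zeros(q)]))
    while len(starts) < n_starts:
        betas = np.tile(beta0, (C, 1))
        betas[:, 0] += rng.normal(scale=2 * np.std(y) + 0.05, size=C)
        betas += rng.normal(scale=0.1 * (np.abs(beta0) + 0.05), size=(C, p))
        logsig = np.log(s0) + rng.normal(scale=0.5, size=C)
        starts.append(np.concatenate([betas.ravel(), logsig,
                                      rng.normal(scale=0.5, size=q)]))
    return starts


def fit_aldvmm(X, y, value_set, n_components: int = 1, *,
               membership: str = "constant", n_starts: int = 20,
               seed: int = 0, feature_names=None,
               maxiter: int = 2000) -> ALDVMMParams:
    """Maximum-likelihood ALDVMM fit with multi-start quasi-Newton search.

    Never raises on optimizer failure: if no start converges the best
    parameters found are returned with ``converged=False`` so that downstream
    model selection can exclude the fit.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    if membership not in ("constant", "covariate"):
        raise ValueError("membership must be 'constant' or 'covariate'")
    X = np.asarray(X, dtype=float)
    y_min, psi = value_set.floor, value_set.truncation_point
    y = _check_support(y, y_min, psi)
    masks = _case_masks(y, y_min, psi)
    n, p = X.shape
    C = n_components
    rng = np.random.default_rng(seed)
    # keep component scales in [5e-3, 4.5]: blocks the degenerate sigma->0
    # likelihood spikes every normal mixture is prone to
    q = 0 if C == 1 else (C - 1) * (p if membership == "covariate" else 1)
    bounds = ([(None, None)] * (C * p) + [(-5.3, 1.5)] * C
              + [(None, None)] * q)
    best_ok = best_any = None
    for theta0 in _starts(X, y, y_min, psi, C, membership, n_starts, rng,
                          feature_names):
        try:
            res = optimize.minimize(
                _negloglik_and_grad, theta0, jac=True,
                args=(X, y, y_min, psi, C, membership, masks),
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-5})
        except (np.linalg.LinAlgError, ValueError):
            continue
        if not np.isfinite(res.fun):
            continue
        if best_any is None or res.fun < best_any.fun:
            best_any = res
        if res.success and (best_ok is None or res.fun < best_ok.fun):
            best_ok = res
    any_ok = best_ok is not None
    best = best_ok if any_ok else best_any
    if best is None:
        return ALDVMMParams(np.zeros((C, p)), np.ones(C),
                            np.zeros(max(C - 1, 0)), y_min, psi,
                            list(feature_names) if feature_names else None,
                            membership, -np.inf, n, converged=False)
    betas, logsig, delta = _unpack(best.x, C, p, membership)
    params = ALDVMMParams(betas, np.exp(logsig),
                          np.asarray(delta), y_min, psi,
                          list(feature_names) if feature_names else None,
                          membership, -float(best.fun), n, converged=any_ok)
    return _sort_components(params)


def _sort_components(params: ALDVMMParams) -> ALDVMMParams:
    """Canonical reporting order: components sorted by intercept."""
    C = params.n_components
    if C == 1:
        return params
    order = np.argsort(params.betas[:, 0])
    if np.array_equal(order, np.arange(C)):
        return params
    if params.membership == "constant":
        logits = np.concatenate([np.ravel(params.delta), [0.0]])[order]
        delta = logits[:-1] - logits[-1]
    else:
        full = np.vstack([np.asarray(params.delta),
                          np.zeros(params.betas.shape[1])])[order]
        delta = full[:-1] - full[-1]
    return ALDVMMParams(params.betas[order], params.sigmas[order], delta,
                        params.y_min, params.psi, params.feature_names,
                        params.membership, params.loglik, params.n,
                        params.converged)


def predict_aldvmm(params: ALDVMMParams, X) -> np.ndarray:
    """Expected utility E[y|x] under the adjusted-normal observation model.

    Per component: mass (1−Φ(b)) at 1, mass Φ(a) at y_min, and the doubly
    censored interior contribution (Φ(b)−Φ(a))μ − σ(φ(b)−φ(a)); the mixture
    expectation is the π-weighted sum, always inside [y_min, 1].
    """
    X = np.asarray(X, dtype=float)
    pi = params.mixture_weights(X)
    out = np.zeros(X.shape[0])
    for c in range(params.n_components):
        mu = X @ params.betas[c]
        s = params.sigmas[c]
        a = (params.y_min - mu) / s
        b = (params.psi - mu) / s
        ec = (norm.sf(b) * 1.0 + norm.cdf(a) * params.y_min
              + (norm.cdf(b) - norm.cdf(a)) * mu
              - s * (norm.pdf(b) - norm.pdf(a)))
        out += pi[:, c] * ec
    return np.clip(out, params.y_min, 1.0)
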