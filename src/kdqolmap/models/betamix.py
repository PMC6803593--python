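"""Two-part mixture beta regression (BETAMIX) for bounded utilities.

Part 1 (discrete): a multinomial logit assigns each record to one of up to
four categories — point mass at the floor y_min, at the truncation point Ψ,
at full health (1), or the continuous interior.  Part 2 (continuous): the
interior utilities, rescaled to z = (y − y_min)/(u − y_min) ∈ (0, 1) with
upper edge u = 1 (default) or u = Ψ (``rescale_to_psi``), follow a K-component
beta mixture with logit-linked component means μ_k(x) = σ(x·γ_k) and
precisions φ_k; the density on the utility scale carries the Jacobian
1/(u − y_min).

The two parts are likelihood-separable, so fitting is exact two-stage ML:
the logit by its own ML (scikit-learn, unpenalised) and the beta mixture by
multi-start quasi-Newton with analytic gradients.

The atom at Ψ is included by default and can be switched off
(``psi_atom=False``), in which case observations at Ψ join the continuous
part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from sklearn.linear_model import LogisticRegression

__all__ = ["BetamixParams", "betamix_loglik", "fit_betamix", "predict_betamix"]

logger = logging.getLogger(__name__)

_EPS_Z = 1e-6
CATEGORIES = ("floor", "psi", "ceiling", "continuous")


@dataclass
class BetamixParams:
    """Fitted two-part beta-mixture parameters.

    ``logit_coefs`` maps category name -> coefficient vector (p,) on the full
    design; categories absent from the training data are omitted and receive
    probability 0.  ``gammas`` has shape (K, p); ``phis`` (K,);
    ``weight_logits`` (K,) constant component logits (last fixed 0 by
    convention after fitting).
    """

    logit_coefs: dict
    gammas: np.ndarray
    phis: np.ndarray
    weight_logits: np.ndarray
    y_min: float
    psi: float
    psi_atom: bool = True
    rescale_to_psi: bool = False
    feature_names: list[str] | None = None
    loglik: float = np.nan
    n: int = 0
    converged: bool = False

    @property
    def n_components(self) -> int:
        return 0 if self.gammas.size == 0 else self.gammas.shape[0]

    @property
    def upper(self) -> float:
        return self.psi if self.rescale_to_psi else 1.0

    def category_probs(self, X) -> dict:
        """Per-record probability of each of the four categories."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        present = [c for c in CATEGORIES if c in self.logit_coefs]
        if len(present) == 1:
            probs = {c: np.zeros(n) for c in CATEGORIES}
            probs[present[0]] = np.ones(n)
            return probs
        eta = np.column_stack([X @ np.asarray(self.logit_coefs[c])
                               for c in present])
        p = special.softmax(eta, axis=1)
        probs = {c: np.zeros(n) for c in CATEGORIES}
        for j, c in enumerate(present):
            probs[c] = p[:, j]
        return probs

    def component_means(self, X) -> np.ndarray:
        """μ_k(x) = expit(x·γ_k), shape (n, K)."""
        return special.expit(np.asarray(X, float) @ self.gammas.T)

    def component_weights(self) -> np.ndarray:
        return special.softmax(self.weight_logits)

    def to_dict(self) -> dict:
        return {"logit_coefs": {c: np.asarray(v).tolist()
                                for c, v in self.logit_coefs.items()},
                "gammas": self.gammas.tolist(), "phis": self.phis.tolist(),
                "weight_logits": self.weight_logits.tolist(),
                "y_min": self.y_min, "psi": self.psi,
                "psi_atom": self.psi_atom,
                "rescale_to_psi": self.rescale_to_psi,
                "feature_names": self.feature_names,
                "loglik": self.loglik, "n": self.n, "converged": self.converged}

    @classmethod
    def from_dict(cls, d) -> "BetamixParams":
        return cls({c: np.asarray(v, float) for c, v in d["logit_coefs"].items()},
                   np.asarray(d["gammas"], float), np.asarray(d["phis"], float),
                   np.asarray(d["weight_logits"], float), float(d["y_min"]),
                   float(d["psi"]), bool(d["psi_atom"]),
                   bool(d["rescale_to_psi"]), d.get("feature_names"),
                   float(d["loglik"]), int(d["n"]), bool(d["converged"]))


def _categorize(y, y_min, psi, psi_atom, tol=1e-9):
    y = np.asarray(y, dtype=float)
    cat = np.full(len(y), "continuous", dtype=object)
    cat[np.abs(y - 1.0) <= tol] = "ceiling"
    cat[np.abs(y - y_min) <= tol] = "floor"
    if psi_atom:
        cat[np.abs(y - psi) <= tol] = "psi"
    bad = (y > psi + tol) & (y < 1.0 - tol)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} outcomes in the infeasible gap ({psi}, 1)")
    if (y < y_min - tol).any() or (y > 1 + tol).any():
        raise ValueError("outcomes outside [y_min, 1]")
    return cat


def _to_unit(y, y_min, upper):
    z = (np.asarray(y, float) - y_min) / (upper - y_min)
    n_clip = int(((z <= 0) | (z >= 1)).sum())
    if n_clip:
        logger.warning("nudged %d rescaled outcomes at the (0,1) edge by %g",
                       n_clip, _EPS_Z)
    return np.clip(z, _EPS_Z, 1.0 - _EPS_Z)


def _beta_mix_nll_grad(theta, X, z, K):
    """Negative log-likelihood and gradient of the K-beta mixture on (0,1)."""
    with np.errstate(over="ignore", invalid="ignore"):
        return _beta_mix_nll_grad_impl(theta, X, z, K)


def _beta_mix_nll_grad_impl(theta, X, z, K):
    n, p = X.shape
    gammas = theta[:K * p].reshape(K, p)
    logphi = theta[K * p:K * p + K]
    wlog = np.concatenate([theta[K * p + K:], [0.0]]) if K > 1 else np.zeros(1)
    phis = np.exp(logphi)
    logw = special.log_softmax(wlog)
    lz, l1z = np.log(z), np.log1p(-z)
    logf = np.empty((n, K))
    dmu_s = np.empty((n, K))   # ∂logf/∂(xγ) via μ=expit
    dlph = np.empty((n, K))    # ∂logf/∂logφ
    for k in range(K):
        mu = special.expit(X @ gammas[k])
        a, b = mu * phis[k], (1 - mu) * phis[k]
        logf[:, k] = (special.gammaln(phis[k]) - special.gammaln(a)
                      - special.gammaln(b) + (a - 1) * lz + (b - 1) * l1z)
        dga = special.digamma(a)
        dgb = special.digamma(b)
        dlogf_dmu = phis[k] * (-dga + dgb + lz - l1z)
        dmu_s[:, k] = dlogf_dmu * mu * (1 - mu)
        dlph[:, k] = phis[k] * (special.digamma(phis[k]) - mu * dga
                                - (1 - mu) * dgb + mu * lz + (1 - mu) * l1z)
    logmix = logw + logf
    ll_i = special.logsumexp(logmix, axis=1)
    w_resp = np.exp(logmix - ll_i[:, None])
    grad = np.empty_like(theta)
    grad[:K * p] = -((w_resp * dmu_s).T @ X).ravel()
    grad[K * p:K * p + K] = -(w_resp * dlph).sum(axis=0)
    if K > 1:
        resid = w_resp - np.exp(logw)[None, :]
        grad[K * p + K:] = -resid[:, :-1].sum(axis=0)
    nll = -float(ll_i.sum())
    if not np.isfinite(nll):
        return 1e12, np.zeros_like(theta)
    return nll, grad


def _logit_loglik(params: BetamixParams, X, cat) -> float:
    probs = params.category_probs(X)
    ll = 0.0
    for c in CATEGORIES:
        m = cat == c
        if m.any():
            ll += float(np.log(np.clip(probs[c][m], 1e-300, None)).sum())
    return ll


def betamix_loglik(params: BetamixParams, X, y) -> float:
    """Full two-part log-likelihood (discrete logit + continuous mixture)."""
    X = np.asarray(X, dtype=float)
    cat = _categorize(y, params.y_min, params.psi, params.psi_atom)
    ll = _logit_loglik(params, X, cat)
    m = cat == "continuous"
    if m.any():
        if params.n_components == 0:
            raise ValueError("continuous observations but no beta components")
        z = _to_unit(np.asarray(y, float)[m], params.y_min, params.upper)
        K, p = params.gammas.shape
        theta = np.concatenate([params.gammas.ravel(), np.log(params.phis),
                                params.weight_logits[:-1] if K > 1 else []])
        nll, _ = _beta_mix_nll_grad(theta, X[m], z, K)
        ll += -nll - m.sum() * np.log(params.upper - params.y_min)
    return ll


def fit_betamix(X, y, value_set, n_components: int = 2, *,
                psi_atom: bool = True, rescale_to_psi: bool = False,
                n_starts: int = 10, seed: int = 0, feature_names=None,
                maxiter: int = 2000) -> BetamixParams:
    """Two-stage ML fit of the two-part beta mixture.

    Returns ``converged=False`` (never raises) when either stage fails.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    y_min, psi = value_set.floor, value_set.truncation_point
    cat = _categorize(y, y_min, psi, psi_atom)
    n, p = X.shape
    upper = psi if rescale_to_psi else 1.0
    # -- discrete part
    present = [c for c in CATEGORIES if (cat == c).any()]
    logit_coefs = {}
    logit_ok = True
    if len(present) == 1:
        logit_coefs[present[0]] = np.zeros(p)
    else:
        labels = np.searchsorted(np.array(sorted(present)), cat.astype(str))
        # C=1e6: effectively unpenalised, but keeps the optimum finite when
        # categories are quasi-separable in a small fold
        clf = LogisticRegression(C=1e6, fit_intercept=False,
                                 max_iter=1000, tol=1e-8)
        try:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X, cat.astype(str))
            coef = clf.coef_
            if len(clf.classes_) == 2:  # sklearn stores one row for binary
                coef = np.vstack([-coef[0] / 2, coef[0] / 2])
            for cls_name, row in zip(clf.classes_, coef):
                logit_coefs[cls_name] = row
        except Exception:
            logit_ok = False
            for c in present:
                logit_coefs[c] = np.zeros(p)
    # -- continuous part
    m = cat == "continuous"
    K = n_components
    cont_ok = True
    if m.sum() == 0:
        gammas = np.zeros((0, p))
        phis = np.zeros(0)
        wlog = np.zeros(0)
        cont_ll = 0.0
    else:
        z = _to_unit(y[m], y_min, upper)
        rng = np.random.default_rng(seed)
        zl = special.logit(z)
        best = None
        for s in range(n_starts):
            g0 = np.zeros((K, p))
            g0[:, 0] = np.quantile(zl, np.linspace(0.25, 0.75, K))
            if s > 0:
                g0 = g0 + rng.normal(scale=0.5, size=(K, p)) * (s > 0)
            lp0 = np.full(K, np.log(10.0)) + (rng.normal(scale=0.5, size=K)
                                              if s > 0 else 0.0)
            theta0 = np.concatenate([g0.ravel(), lp0,
                                     np.zeros(K - 1) if K > 1 else []])
            # precision bounded in [e^-1, e^8]: blocks degenerate spikes
            bnds = ([(None, None)] * (K * p) + [(-1.0, 8.0)] * K
                    + [(None, None)] * (K - 1 if K > 1 else 0))
            try:
                res = optimize.minimize(
                    _beta_mix_nll_grad, theta0, jac=True, args=(X[m], z, K),
                    method="L-BFGS-B", bounds=bnds,
                    options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-5})
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not np.isfinite(res.fun):
                continue
            if best is None or (res.success and not best.success) or \
               (res.success == best.success and res.fun < best.fun):
                best = res
        if best is None:
            gammas, phis, wlog = np.zeros((K, p)), np.ones(K), np.zeros(K)
            cont_ll = -np.inf
            cont_ok = False
        else:
            cont_ok = bool(best.success)
            gammas = best.x[:K * p].reshape(K, p)
            phis = np.exp(best.x[K * p:K * p + K])
            wlog = np.concatenate([best.x[K * p + K:], [0.0]]) if K > 1 \
                else np.zeros(1)
            cont_ll = -best.fun - m.sum() * np.log(upper - y_min)
            # canonical order: components sorted by mean-link intercept
            order = np.argsort(gammas[:, 0])
            gammas, phis = gammas[order], phis[order]
            wlog = wlog[order] - wlog[order][-1]
    params = BetamixParams(logit_coefs, gammas, phis, wlog, y_min, psi,
                           psi_atom, rescale_to_psi,
                           list(feature_names) if feature_names else None,
                           np.nan, n, converged=logit_ok and cont_ok)
    params.loglik = _logit_loglik(params, X, cat) + \
        (cont_ll if m.sum() else 0.0)
    return params


def predict_betamix(params: BetamixParams, X) -> np.ndarray:
    """Expected utility: category-probability-weighted atoms plus the
    continuous conditional mean; always inside [y_min, 1]."""
    X = np.asarray(X, dtype=float)
    probs = params.category_probs(X)
    out = (probs["ceiling"] * 1.0 + probs["psi"] * params.psi
           + probs["floor"] * params.y_min)
    pc = probs["continuous"]
    if params.n_components and pc.max() > 0:
        mu = params.component_means(X)
        w = params.component_weights()
        cond = params.y_min + (params.upper - params.y_min) * (mu @ w)
        out = out + pc * cond
    elif pc.max() > 0:
        # no continuous component fitted: fall back to interior midpoint
        out = out + pc * 0.5 * (params.y_min + params.upper)
    return np.clip(out, params.y_min, 1.0)
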