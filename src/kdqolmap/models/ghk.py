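"""GHK recursive importance sampler for multivariate-normal rectangle
probabilities.

Computes P(a_j < ε_j ≤ b_j, j = 1..d) for ε ~ MVN(0, R) by the
Geweke–Hajivassiliou–Keane recursion: factor R = LLᵀ, then sample each
truncated conditional in turn and accumulate the product of conditional
interval probabilities.  Draws are scrambled Halton points with antithetic
pairing, fixed by seed, so results are deterministic given (draws, seed).

When R = I the conditional bounds do not depend on the draws and the GHK
estimate is *exact* — it reduces to the product of the univariate interval
probabilities — which the independent-probit oracle tests exploit.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import qmc
from scipy.special import ndtr, ndtri

__all__ = ["ghk_draws", "ghk_probs"]

_TINY = 1e-300
_UCLIP = 1e-12


def ghk_draws(n_draws: int, dim: int = 5, seed: int = 0) -> np.ndarray:
    """Antithetic scrambled-Halton uniforms, shape (n_draws, dim-1).

    Only dim−1 uniform coordinates are needed: the last dimension contributes
    a probability factor but no further conditioning draw.
    """
    if n_draws % 2:
        raise ValueError("n_draws must be even (antithetic pairing)")
    sampler = qmc.Halton(d=dim - 1, scramble=True, seed=seed)
    u = sampler.random(n_draws // 2)
    u = np.vstack([u, 1.0 - u])
    return np.clip(u, _UCLIP, 1 - _UCLIP)


def ghk_probs(lower: np.ndarray, upper: np.ndarray, chol: np.ndarray,
              u: np.ndarray) -> np.ndarray:
    """GHK rectangle probabilities for a batch of bounds.

    Parameters
    ----------
    lower, upper : (batch, d) bounds on the correlated latent ε (may be ±inf).
    chol : (d, d) lower Cholesky factor of the correlation matrix.
    u : (n_draws, d-1) uniforms from :func:`ghk_draws`.

    Returns (batch,) probability estimates in [0, 1].
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    batch, d = lower.shape
    m = u.shape[0]
    # eta: sampled truncated-normal innovations, shape (batch, m)
    eta = np.zeros((d - 1, batch, m))
    prob = np.ones((batch, m))
    for j in range(d):
        ljj = chol[j, j]
        if j == 0:
            lo = np.broadcast_to((lower[:, 0] / ljj)[:, None], (batch, m))
            hi = np.broadcast_to((upper[:, 0] / ljj)[:, None], (batch, m))
        else:
            cond = np.tensordot(chol[j, :j], eta[:j], axes=(0, 0))
            lo = (lower[:, j][:, None] - cond) / ljj
            hi = (upper[:, j][:, None] - cond) / ljj
        plo = ndtr(lo)
        phi_ = ndtr(hi)
        pj = np.clip(phi_ - plo, _TINY, 1.0)
        prob *= pj
        if j < d - 1:
            q = plo + u[:, j][None, :] * (phi_ - plo)
            eta[j] = ndtri(np.clip(q, _UCLIP, 1 - _UCLIP))
    return prob.mean(axis=1)
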