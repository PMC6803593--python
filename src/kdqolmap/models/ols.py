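"""Ordinary least squares direct mapping.

OLS regresses the EQ-5D index itself on the explanatory scores.  Its
predictions are deliberately left unclamped: a linear predictor can fall
outside the feasible utility range, and that behaviour is part of what the
model-comparison exercise measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OLSFit", "fit_ols"]


@dataclass
class OLSFit:
    coefficients: np.ndarray
    feature_names: list[str]
    residual_sd: float
    loglik: float
    n: int
    converged: bool = True  # closed form: always

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coefficients

    def to_dict(self) -> dict:
        return {"coefficients": self.coefficients.tolist(),
                "feature_names": list(self.feature_names),
                "residual_sd": self.residual_sd,
                "loglik": self.loglik, "n": self.n,
                "converged": self.converged}

    @classmethod
    def from_dict(cls, d) -> "OLSFit":
        return cls(np.asarray(d["coefficients"], dtype=float),
                   list(d["feature_names"]), float(d["residual_sd"]),
                   float(d["loglik"]), int(d["n"]), bool(d["converged"]))


def fit_ols(X, y, feature_names=None) -> OLSFit:
    """Least-squares fit; raises on rank deficiency naming collinear columns.

    Equal (to numerical precision) to the normal-equation solution
    (XᵀX)⁻¹Xᵀy, but computed via a rank-revealing least-squares solve.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    names = list(feature_names) if feature_names is not None else \
        [f"x{j}" for j in range(p)]
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        # identify columns not pivoted by QR
        _, r, piv = _qr_pivot(X)
        dropped = sorted(piv[rank:])
        raise np.linalg.LinAlgError(
            f"design matrix rank {rank} < {p}; collinear columns: "
            f"{[names[j] for j in dropped]}")
    resid = y - X @ beta
    sigma = float(np.sqrt(np.mean(resid ** 2)))
    ll = float(-0.5 * n * (np.log(2 * np.pi * max(sigma, 1e-300) ** 2) + 1.0))
    return OLSFit(beta, names, sigma, ll, n)


def _qr_pivot(X):
    from scipy.linalg import qr
    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv
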