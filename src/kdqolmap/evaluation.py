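"""Cross-validation, error metrics, rank-sum model selection, correlations.

Model comparison protocol: 10-fold cross-validation with one shared fold
assignment per dataset (so all models see identical splits); out-of-fold
predictions are pooled over all records and summarised as

    ME   = mean(pred − obs)        (sign convention: predicted minus observed)
    MAE  = mean|pred − obs|
    RMSE = sqrt(mean((pred − obs)²))

Models are ranked on MAE and on RMSE, the two ranks are summed, and the model
with the smallest rank sum wins; ties on the rank sum are broken by the
lower RMSE.  Non-converged models are excluded from ranking and listed
separately.

Within each metric column, ties at the printed precision are broken by the
*other* metric and then by grid order (``ties="other_metric"``, the default);
plain minimum (competition) ranking is available with ``ties="min"``.

Spearman correlations between instruments are banded as low (0.30–0.49),
moderate (0.50–0.69), high (0.70–0.89) and very high (0.90–1); |rho| < 0.30
is reported as below-low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CVMetrics", "ModelRanking", "kfold_split", "prediction_metrics",
           "cross_validate", "rank_models", "spearman_rho", "band",
           "CorrelationBand"]

_BAND_EDGES = (0.30, 0.50, 0.70, 0.90)
_BAND_NAMES = ("below-low", "low", "moderate", "high", "very high")


@dataclass
class CVMetrics:
    """Pooled out-of-fold prediction-error summary for one model."""

    model_id: str
    me: float
    mae: float
    rmse: float
    n_predictions: int
    converged: bool = True

    def __post_init__(self):
        if self.converged and np.isfinite(self.mae):
            if not (self.rmse >= self.mae - 1e-12 and self.mae >= 0
                    and abs(self.me) <= self.mae + 1e-12):
                raise ValueError(
                    f"inconsistent metrics for {self.model_id}: "
                    f"ME={self.me}, MAE={self.mae}, RMSE={self.rmse}")


@dataclass
class ModelRanking:
    """Rank-sum selection table over converged models."""

    table: pd.DataFrame          # model_id, me, mae, rmse, mae_rank, rmse_rank, rank_sum, final_rank
    selected: str                # model_id with final_rank 1
    excluded: list = field(default_factory=list)  # non-converged model ids


def kfold_split(n: int, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Random partition of 0..n−1 into k groups with sizes differing by ≤ 1."""
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return list(np.array_split(perm, k))


def prediction_metrics(observed, predicted) -> tuple[float, float, float]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    err = pred - obs
    return (float(err.mean()), float(np.abs(err).mean()),
            float(np.sqrt((err ** 2).mean())))


def cross_validate(fit_predict, data: pd.DataFrame, y: np.ndarray,
                   model_id: str = "model", k: int = 10, seed: int = 0,
                   folds=None, per_fold: bool = False) -> CVMetrics:
    """k-fold cross-validation of one model.

    ``fit_predict(train_data, train_y, test_data) -> predictions | None``
    fits on the training split and predicts the held-out split; returning
    ``None`` (or raising) marks the whole model non-converged — the grid
    carries on.  ``folds`` allows a shared pre-computed split.  ``per_fold``
    averages metrics across folds instead of pooling predictions (an option;
    pooling is the default).
    """
    n = len(data)
    if folds is None:
        folds = kfold_split(n, k, seed)
    pred = np.full(n, np.nan)
    fold_metrics = []
    for test_idx in folds:
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        try:
            p = fit_predict(data.iloc[~mask], y[~mask], data.iloc[mask])
        except Exception:
            p = None
        if p is None or not np.all(np.isfinite(p)):
            return CVMetrics(model_id, np.nan, np.nan, np.nan, 0,
                             converged=False)
        pred[mask] = p
        if per_fold:
            fold_metrics.append(prediction_metrics(y[mask], p))
    if per_fold:
        me, mae, rmse = (float(np.mean([m[i] for m in fold_metrics]))
                         for i in range(3))
    else:
        me, mae, rmse = prediction_metrics(y, pred)
    return CVMetrics(model_id, me, mae, rmse, n, converged=True)


def _ordinal_rank(df: pd.DataFrame, primary: str, secondary: str,
                  ties: str) -> np.ndarray:
    if ties == "min":
        return df[primary].rank(method="min").to_numpy(dtype=int)
    order = np.lexsort((np.arange(len(df)), df[secondary].to_numpy(),
                        df[primary].to_numpy()))
    ranks = np.empty(len(df), dtype=int)
    ranks[order] = np.arange(1, len(df) + 1)
    return ranks


def rank_models(metrics: list[CVMetrics], ties: str = "other_metric"
                ) -> ModelRanking:
    """Rank-sum model selection with RMSE tie-break on the final ordering."""
    converged = [m for m in metrics if m.converged]
    excluded = [m.model_id for m in metrics if not m.converged]
    if not converged:
        raise ValueError("no converged models to rank")
    df = pd.DataFrame({"model_id": [m.model_id for m in converged],
                       "me": [m.me for m in converged],
                       "mae": [m.mae for m in converged],
                       "rmse": [m.rmse for m in converged]})
    df["mae_rank"] = _ordinal_rank(df, "mae", "rmse", ties)
    df["rmse_rank"] = _ordinal_rank(df, "rmse", "mae", ties)
    df["rank_sum"] = df["mae_rank"] + df["rmse_rank"]
    df["final_rank"] = _ordinal_rank(df, "rank_sum", "rmse", "other_metric")
    df = df.sort_values("final_rank").reset_index(drop=True)
    return ModelRanking(df, selected=df.loc[0, "model_id"], excluded=excluded)


@dataclass(frozen=True)
class CorrelationBand:
    rho: float
    band: str


def band(rho: float) -> str:
    """Band an absolute correlation per the 0.30/0.50/0.70/0.90 thresholds."""
    r = abs(rho)
    if r > 1 + 1e-12:
        raise ValueError("rho outside [-1, 1]")
    idx = sum(r >= e for e in _BAND_EDGES)
    return _BAND_NAMES[idx]


def spearman_rho(x, y) -> CorrelationBand:
    """Spearman rank correlation (average ranks for ties) with its band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    return CorrelationBand(rho, band(rho))
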