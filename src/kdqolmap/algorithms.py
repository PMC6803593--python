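"""Model-grid orchestration and portable mapping algorithms.

``run_grid`` fits the full candidate grid — OLS, BETAMIX and SUROPM over the
two variable sets × three expansions, plus ALDVMM over the same six designs ×
1–3 components (36 candidates) — cross-validates every entry on one shared
fold assignment, ranks the converged entries by MAE/RMSE rank sum, and
persists the winner as a :class:`MappingAlgorithm`.

A ``MappingAlgorithm`` is a self-contained JSON artifact: applying it to new
respondents needs only their KDQOL-36 scores, age and sex.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import DesignSpec, build_design, scale_features
from .evaluation import (CVMetrics, ModelRanking, cross_validate, kfold_split,
                         rank_models, spearman_rho)
from .kdqol import SCORE_COLUMNS
from .models import (fit_aldvmm, fit_betamix, fit_ols, fit_suropm,
                     predict_aldvmm, predict_betamix,
                     predict_utility_response)
from .models.aldvmm import ALDVMMParams
from .models.betamix import BetamixParams
from .models.ols import OLSFit
from .models.suropm import SUROPMParams
from .valuesets import ValueSet

__all__ = ["MappingAlgorithm", "GridEntry", "GridResult", "grid_entries",
           "run_grid", "apply_algorithm", "correlate"]

logger = logging.getLogger(__name__)

ITEM_COLUMNS = ("mo", "sc", "ua", "pd", "ad")

# grid shorthand: spec index 1..6 = the six designs in table order
_SPECS = [DesignSpec("summary", "main"), DesignSpec("summary", "sq"),
          DesignSpec("summary", "sqint"), DesignSpec("subscales", "main"),
          DesignSpec("subscales", "sq"), DesignSpec("subscales", "sqint")]

_PARAM_CLASSES = {"ols": OLSFit, "betamix": BetamixParams,
                  "aldvmm": ALDVMMParams, "suropm": SUROPMParams}


@dataclass(frozen=True)
class GridEntry:
    model_id: str
    model_type: str            # ols | betamix | aldvmm | suropm
    spec: DesignSpec
    components: int | None = None


def grid_entries(components=(1, 2, 3), families=("ols", "betamix", "aldvmm",
                                                 "suropm")) -> list[GridEntry]:
    """The candidate grid: 6+6+6 single-fit families + 6×|components| ALDVMM."""
    out = []
    for fam, tag in (("ols", "OLS"), ("betamix", "BETA")):
        if fam in families:
            out += [GridEntry(f"{tag} {i+1}", fam, s)
                    for i, s in enumerate(_SPECS)]
    if "aldvmm" in families:
        out += [GridEntry(f"ALD {i+1}-{c}", "aldvmm", s, c)
                for i, s in enumerate(_SPECS) for c in components]
    if "suropm" in families:
        out += [GridEntry(f"OPM {i+1}", "suropm", s)
                for i, s in enumerate(_SPECS)]
    return out


@dataclass
class MappingAlgorithm:
    """A fitted, portable KDQOL-36 -> EQ-5D mapping function."""

    model_type: str
    spec: DesignSpec
    params: object
    value_set: ValueSet
    provenance: dict = field(default_factory=dict)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X = build_design(data, self.spec)
        Xs, _ = scale_features(X)
        if self.model_type == "ols":
            return self.params.predict(Xs.to_numpy())
        if self.model_type == "aldvmm":
            return predict_aldvmm(self.params, Xs.to_numpy())
        if self.model_type == "betamix":
            return predict_betamix(self.params, Xs.to_numpy())
        if self.model_type == "suropm":
            return predict_utility_response(self.params, Xs.to_numpy(),
                                            self.value_set)
        raise ValueError(f"unknown model_type {self.model_type!r}")

    def to_dict(self) -> dict:
        return {"model_type": self.model_type,
                "design_spec": self.spec.to_dict(),
                "value_set": self.value_set.to_dict(),
                "value_set_snapshot": {
                    "name": self.value_set.name,
                    "version": self.value_set.version,
                    "floor": self.value_set.floor,
                    "truncation_point": self.value_set.truncation_point},
                "parameters": self.params.to_dict(),
                "provenance": self.provenance,
                "package_version": __version__}

    @classmethod
    def from_dict(cls, d) -> "MappingAlgorithm":
        params = _PARAM_CLASSES[d["model_type"]].from_dict(d["parameters"])
        return cls(d["model_type"], DesignSpec.from_dict(d["design_spec"]),
                   params, ValueSet.from_dict(d["value_set"]),
                   d.get("provenance", {}))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "MappingAlgorithm":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def export_excel(self, path) -> None:
        """Convenience coefficient sheet (formula-free); JSON is the source
        of truth."""
        import openpyxl
        wb = openpyxl.Workbook()
        ws = wb.active
        ws.title = "coefficients"
        ws.append(["model_type", self.model_type])
        ws.append(["design", self.spec.label])
        ws.append(["value_set", self.value_set.name])
        ws.append([])
        d = self.params.to_dict()
        for key, val in d.items():
            ws.append([key, json.dumps(val) if isinstance(val, (list, dict))
                       else val])
        wb.save(path)


def dataset_fingerprint(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes())
    return h.hexdigest()[:16]


def _fit_entry(entry: GridEntry, train: pd.DataFrame, y_train, vs: ValueSet,
               seed: int, aldvmm_starts: int, betamix_K: int,
               suropm_draws: int, suropm_refine: str):
    """Fit one grid entry; returns (params, predict_fn) or raises."""
    Xs_train, _ = scale_features(build_design(train, entry.spec))
    names = list(Xs_train.columns)
    if entry.model_type == "ols":
        fit = fit_ols(Xs_train.to_numpy(), y_train, names)
        return fit, lambda Xs, test: fit.predict(Xs)
    if entry.model_type == "betamix":
        fit = fit_betamix(Xs_train.to_numpy(), y_train, vs, betamix_K,
                          seed=seed, feature_names=names)
        if not fit.converged:
            raise RuntimeError(f"{entry.model_id}: non-convergence")
        return fit, lambda Xs, test: predict_betamix(fit, Xs)
    if entry.model_type == "aldvmm":
        fit = fit_aldvmm(Xs_train.to_numpy(), y_train, vs, entry.components,
                         n_starts=aldvmm_starts, seed=seed,
                         feature_names=names)
        if not fit.converged:
            raise RuntimeError(f"{entry.model_id}: non-convergence")
        return fit, lambda Xs, test: predict_aldvmm(fit, Xs)
    if entry.model_type == "suropm":
        resp = train[list(ITEM_COLUMNS)].to_numpy(dtype=int)
        L = 3 if vs.version == "3L" else 5
        fit = fit_suropm(Xs_train.to_numpy(), resp, L, n_draws=suropm_draws,
                         ghk_seed=seed, refine=suropm_refine,
                         feature_names=names)
        if not fit.converged:
            raise RuntimeError(f"{entry.model_id}: non-convergence")
        return fit, lambda Xs, test: predict_utility_response(fit, Xs, vs)
    raise ValueError(entry.model_type)


@dataclass
class GridResult:
    metrics: list
    ranking: ModelRanking
    selected: MappingAlgorithm
    report: pd.DataFrame


def run_grid(data: pd.DataFrame, value_set: ValueSet, *, k: int = 10,
             seed: int = 0, components=(1, 2, 3), betamix_K: int = 2,
             aldvmm_starts: int = 3, suropm_draws: int = 100,
             suropm_refine: str = "none",
             families=("ols", "betamix", "aldvmm", "suropm"),
             fault_injector=None) -> GridResult:
    """Cross-validate the whole grid and select the rank-1 algorithm.

    Per-entry failures (including any fold's non-convergence) mark the entry
    non-converged and excluded from ranking; they never abort the grid.
    ``fault_injector(model_id) -> bool`` is a testing hook that forces an
    entry to be treated as non-convergent.
    """
    vs = value_set
    if "eq5d_index" not in data.columns:
        raise ValueError("dataset needs an eq5d_index column")
    y = data["eq5d_index"].to_numpy(dtype=float)
    have_items = all(c in data.columns for c in ITEM_COLUMNS)
    entries = grid_entries(components, families)
    folds = kfold_split(len(data), k, seed)
    metrics, meta = [], {}
    for entry in entries:
        meta[entry.model_id] = entry
        if entry.model_type == "suropm" and not have_items:
            logger.warning("%s skipped: no item response columns",
                           entry.model_id)
            metrics.append(CVMetrics(entry.model_id, np.nan, np.nan, np.nan,
                                     0, converged=False))
            continue
        if fault_injector is not None and fault_injector(entry.model_id):
            metrics.append(CVMetrics(entry.model_id, np.nan, np.nan, np.nan,
                                     0, converged=False))
            continue

        def fit_predict(train, y_train, test, entry=entry):
            _, predict = _fit_entry(entry, train, y_train, vs, seed,
                                    aldvmm_starts, betamix_K, suropm_draws,
                                    suropm_refine)
            Xs_test, _ = scale_features(build_design(test, entry.spec))
            return predict(Xs_test.to_numpy(), test)

        m = cross_validate(fit_predict, data, y, entry.model_id, k=k,
                           seed=seed, folds=folds)
        if not m.converged:
            logger.warning("%s: excluded (non-convergence in a fold)",
                           entry.model_id)
        metrics.append(m)
    ranking = rank_models(metrics)
    best_id = ranking.selected
    best = meta[best_id]
    params, _ = _fit_entry(best, data, y, vs, seed, max(aldvmm_starts, 10),
                           betamix_K, suropm_draws, suropm_refine)
    row = ranking.table.loc[ranking.table.model_id == best_id].iloc[0]
    algo = MappingAlgorithm(
        best.model_type, best.spec, params, vs,
        provenance={"seed": seed, "k": k, "n": len(data),
                    "dataset_fingerprint": dataset_fingerprint(data),
                    "cv_metrics": {"me": float(row.me), "mae": float(row.mae),
                                   "rmse": float(row.rmse)},
                    "model_id": best_id})
    report = _grid_report(metrics, meta, ranking)
    return GridResult(metrics, ranking, algo, report)


def _grid_report(metrics, meta, ranking: ModelRanking) -> pd.DataFrame:
    ranked = ranking.table.set_index("model_id")
    rows = []
    for m in metrics:
        e = meta[m.model_id]
        row = {"model_id": m.model_id, "model_type": e.model_type,
               "variable_set": e.spec.variable_set,
               "expansion": e.spec.expansion,
               "components": e.components,
               "me": m.me, "mae": m.mae, "rmse": m.rmse,
               "converged": m.converged}
        if m.model_id in ranked.index:
            r = ranked.loc[m.model_id]
            row.update(mae_rank=int(r.mae_rank), rmse_rank=int(r.rmse_rank),
                       final_rank=int(r.final_rank))
        else:
            row.update(mae_rank=None, rmse_rank=None, final_rank=None)
        rows.append(row)
    return pd.DataFrame(rows)


def apply_algorithm(algo: MappingAlgorithm, data: pd.DataFrame
                    ) -> pd.DataFrame:
    """Predict one utility per row; rows with missing required inputs get a
    row-level error entry instead of aborting the batch."""
    required = list(algo.spec.scores) + ["age", "sex"]
    missing_cols = [c for c in required if c not in data.columns]
    if missing_cols:
        raise ValueError(f"input missing required columns: {missing_cols}")
    ok = ~data[required].isna().any(axis=1)
    out = pd.DataFrame(index=data.index)
    out["prediction"] = np.nan
    out["error"] = ""
    if ok.any():
        out.loc[ok, "prediction"] = algo.predict(data.loc[ok])
    for idx in data.index[~ok]:
        bad = [c for c in required if pd.isna(data.loc[idx, c])]
        out.loc[idx, "error"] = f"missing: {', '.join(bad)}"
    return out


def correlate(data: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho + band for every score×outcome, score×score and
    item×item pair.

    KDCS×{Symptoms, Effects, Burden} pairs are excluded from the score×score
    block (KDCS is their average, the correlation is structural).  Constant
    columns are flagged rather than dropped silently.
    """
    scores = [c for c in list(SCORE_COLUMNS) + ["kdcs"] if c in data.columns]
    targets = [c for c in ("eq5d_index",) + ITEM_COLUMNS if c in data.columns]
    rows = []

    def add(block, a, b):
        try:
            cb = spearman_rho(data[a], data[b])
            rows.append({"block": block, "var1": a, "var2": b,
                         "rho": cb.rho, "band": cb.band, "note": ""})
        except ValueError as e:
            rows.append({"block": block, "var1": a, "var2": b,
                         "rho": np.nan, "band": "", "note": str(e)})

    for s in scores:
        for t in targets:
            add("score_x_outcome", s, t)
    structural = {frozenset(("kdcs", c))
                  for c in ("symptoms", "effects", "burden")}
    for a, b in combinations(scores, 2):
        if frozenset((a, b)) in structural:
            continue
        add("score_x_score", a, b)
    items = [c for c in ITEM_COLUMNS if c in data.columns]
    for a, b in combinations(items, 2):
        add("item_x_item", a, b)
    return pd.DataFrame(rows)
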