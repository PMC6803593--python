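"""Regressor construction for the mapping-model grid.

Two explanatory-variable sets are used throughout: the *summary* set
(PCS, MCS, KDCS) and the *subscales* set (PCS, MCS, Symptoms, Effects,
Burden), each with three polynomial expansions — main effects only, plus
squares, plus squares and all two-way interactions of the KDQOL scores.
Age and sex enter every model additively and are never squared or interacted.

Feature order is deterministic: intercept, main effects, squares,
interactions, age, sex (male = 1, female = 0).  Feature counts per expansion:
summary set {6, 9, 12}, subscales set {8, 13, 23}.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DesignSpec", "build_design", "scale_features", "unscale_coefficients"]

_VARIABLE_SETS = {
    "summary": ("pcs", "mcs", "kdcs"),
    "subscales": ("pcs", "mcs", "symptoms", "effects", "burden"),
}
_EXPANSIONS = ("main", "sq", "sqint")

# internal scaling divisors for optimizer stability (scores/100, age/10)
_SCORE_DIV = 100.0
_AGE_DIV = 10.0


@dataclass(frozen=True)
class DesignSpec:
    """One model's regressor recipe: variable set x polynomial expansion."""

    variable_set: str = "subscales"
    expansion: str = "main"

    def __post_init__(self):
        if self.variable_set not in _VARIABLE_SETS:
            raise ValueError(f"variable_set must be one of {sorted(_VARIABLE_SETS)}")
        if self.expansion not in _EXPANSIONS:
            raise ValueError(f"expansion must be one of {_EXPANSIONS}")

    @property
    def scores(self) -> tuple[str, ...]:
        return _VARIABLE_SETS[self.variable_set]

    def feature_names(self, intercept: bool = True) -> list[str]:
        names = ["const"] if intercept else []
        names += list(self.scores)
        if self.expansion in ("sq", "sqint"):
            names += [f"{s}^2" for s in self.scores]
        if self.expansion == "sqint":
            names += [f"{a}*{b}" for a, b in itertools.combinations(self.scores, 2)]
        names += ["age", "sex_male"]
        return names

    @property
    def label(self) -> str:
        return f"{self.variable_set}/{self.expansion}"

    def to_dict(self) -> dict:
        return {"variable_set": self.variable_set, "expansion": self.expansion}

    @classmethod
    def from_dict(cls, d) -> "DesignSpec":
        return cls(d["variable_set"], d["expansion"])


def _sex_to_male(sex) -> np.ndarray:
    s = pd.Series(sex)
    if s.dtype == object:
        return (s == "male").to_numpy(dtype=float)
    return s.to_numpy(dtype=float)


def build_design(data: pd.DataFrame, spec: DesignSpec,
                 intercept: bool = True) -> pd.DataFrame:
    """Build the named design matrix for ``spec`` from a respondent table.

    Squares and interactions are computed from the original-scale scores, so
    the output is reproducible bit-for-bit given a dataset.  Raises on any
    missing required column or missing value.
    """
    cols = {}
    for s in spec.scores:
        if s not in data.columns:
            raise ValueError(f"required score column {s!r} missing for {spec.label}")
        cols[s] = data[s].to_numpy(dtype=float)
    for extra in ("age",):
        if extra not in data.columns:
            raise ValueError("required column 'age' missing")
    if "sex" not in data.columns:
        raise ValueError("required column 'sex' missing")
    out = {}
    if intercept:
        out["const"] = np.ones(len(data))
    for s in spec.scores:
        out[s] = cols[s]
    if spec.expansion in ("sq", "sqint"):
        for s in spec.scores:
            out[f"{s}^2"] = cols[s] ** 2
    if spec.expansion == "sqint":
        for a, b in itertools.combinations(spec.scores, 2):
            out[f"{a}*{b}"] = cols[a] * cols[b]
    out["age"] = data["age"].to_numpy(dtype=float)
    out["sex_male"] = _sex_to_male(data["sex"])
    X = pd.DataFrame(out, index=data.index)
    if X.isna().to_numpy().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in design columns {bad}")
    return X


def _column_divisor(name: str) -> float:
    if name in ("const", "sex_male"):
        return 1.0
    if name == "age":
        return _AGE_DIV
    if name.endswith("^2"):
        return _SCORE_DIV ** 2
    if "*" in name:
        return _SCORE_DIV ** 2
    return _SCORE_DIV


def scale_features(X: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Divide score columns by 100 (squares/interactions by 100²) and age by 10.

    Returns the scaled matrix and the per-column divisor vector; dividing the
    scaled-fit coefficients by the same vector restores original units, and
    predictions are invariant to the scaling.
    """
    div = np.array([_column_divisor(c) for c in X.columns])
    return X / div, div


def unscale_coefficients(beta_scaled: np.ndarray, divisors: np.ndarray) -> np.ndarray:
    """Map coefficients fitted on scaled features back to original units."""
    return np.asarray(beta_scaled) / np.asarray(divisors)
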