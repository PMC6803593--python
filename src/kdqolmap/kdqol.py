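"""KDQOL-36 score data model.

The KDQOL-36 combines the generic SF-12 (yielding the norm-based physical and
mental component summaries, PCS and MCS) with 24 kidney-disease-specific items
grouped into three subscales — Symptoms/problems (12 items), Effects of kidney
disease (8 items) and Burden of kidney disease (4 items) — each linearly
rescaled to 0–100, higher = better.  The kidney disease component summary
(KDCS) is the unweighted mean of the three subscale scores.

PCS and MCS are *inputs* here, not computed: the SF-12 summary scoring relies
on proprietary norm-based weights distributed by the instrument developer, and
the mapping pipeline only needs the resulting scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KDQOL36Scores",
    "Covariates",
    "compute_kdcs",
    "rescale_subscale",
    "validate_scores",
    "load_dataset",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = ("pcs", "mcs", "symptoms", "effects", "burden")


@dataclass(frozen=True)
class KDQOL36Scores:
    """One respondent's KDQOL-36 subscale scores (all on 0–100)."""

    pcs: float
    mcs: float
    symptoms: float
    effects: float
    burden: float

    def __post_init__(self):
        for name in SCORE_COLUMNS:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")

    @property
    def kdcs(self) -> float:
        return compute_kdcs(self.symptoms, self.effects, self.burden)


@dataclass(frozen=True)
class Covariates:
    """Demographic covariates entering every mapping model."""

    age: float
    sex: str  # "male" | "female"

    def __post_init__(self):
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


def compute_kdcs(symptoms, effects, burden):
    """Kidney disease component summary: mean of the three subscale scores.

    Accepts scalars or arrays; every input must lie in [0, 100].
    """
    s = np.asarray(symptoms, dtype=float)
    e = np.asarray(effects, dtype=float)
    b = np.asarray(burden, dtype=float)
    for name, arr in (("symptoms", s), ("effects", e), ("burden", b)):
        if np.any(np.isnan(arr)):
            raise ValueError(f"{name} contains missing values")
        if np.any((arr < 0) | (arr > 100)):
            raise ValueError(f"{name} outside [0, 100]")
    out = (s + e + b) / 3.0
    return float(out) if out.ndim == 0 else out


def rescale_subscale(item_responses: Sequence, recode: Mapping,
                     skip_missing: bool = False) -> float:
    """Score one subscale: recode each item to 0–100, then average.

    Parameters
    ----------
    item_responses : sequence of raw coded levels (None/NaN = missing).
    recode : map from raw level to its 0–100 value.  A per-item list of maps
        is also accepted.
    skip_missing : if True, average the available recoded items (an option,
        not the default: the default policy excludes incomplete records).
    """
    maps = recode if isinstance(recode, (list, tuple)) else [recode] * len(item_responses)
    if len(maps) != len(item_responses):
        raise ValueError("one recode map per item required")
    vals = []
    for i, (resp, m) in enumerate(zip(item_responses, maps)):
        if resp is None or (isinstance(resp, float) and np.isnan(resp)):
            if skip_missing:
                continue
            raise ValueError(f"item {i}: missing response")
        if resp not in m:
            raise ValueError(f"item {i}: level {resp!r} not in recode map")
        v = float(m[resp])
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"item {i}: recoded value {v} outside [0, 100]")
        vals.append(v)
    if not vals:
        raise ValueError("no non-missing items")
    return float(np.mean(vals))


def linear_recode(levels: Sequence, best_last: bool = True) -> dict:
    """Equal-spaced linear recoding of ordered levels onto 0–100."""
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two levels")
    step = 100.0 / (k - 1)
    vals = [i * step for i in range(k)]
    if not best_last:
        vals = vals[::-1]
    return dict(zip(levels, vals))


def validate_scores(record: Mapping, kdcs_tol: float = 0.01) -> dict:
    """Validate one respondent record; never silently repairs.

    Returns ``{"ok": bool, "errors": [...], "warnings": [...]}``.  If the
    record carries both a ``kdcs`` and the three subscales, the supplied KDCS
    is cross-checked against the recomputed mean (tolerance ``kdcs_tol``).
    """
    errors, warnings = [], []
    for name in SCORE_COLUMNS:
        v = record.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            errors.append(f"{name}: missing")
        elif not 0.0 <= float(v) <= 100.0:
            errors.append(f"{name}: value {v} outside [0, 100]")
    age = record.get("age")
    if age is None:
        errors.append("age: missing")
    elif not float(age) > 0:
        errors.append(f"age: {age} not positive")
    sex = record.get("sex")
    if sex not in ("male", "female", 0, 1):
        errors.append(f"sex: {sex!r} not recognised")
    if "kdcs" in record and record["kdcs"] is not None and not errors:
        expected = compute_kdcs(record["symptoms"], record["effects"],
                                record["burden"])
        if abs(float(record["kdcs"]) - expected) > kdcs_tol:
            errors.append(
                f"kdcs: supplied {record['kdcs']} inconsistent with "
                f"subscale mean {expected:.4f}")
    return {"ok": not errors, "errors": errors, "warnings": warnings}


def load_dataset(path, require_outcome: bool = True,
                 logger=None) -> pd.DataFrame:
    """Load a respondent CSV and apply the complete-case policy.

    Expected columns: ``id, pcs, mcs, symptoms, effects, burden, [kdcs],
    age, sex`` plus either ``eq5d_index`` or the five item responses
    ``mo, sc, ua, pd, ad`` (with the value-set name supplied separately).
    Records with any required score missing are dropped with a logged count;
    a ``kdcs`` column is recomputed (and cross-checked) from the subscales.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = list(SCORE_COLUMNS) + ["age", "sex"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"dataset missing required columns: {missing_cols}")
    has_index = "eq5d_index" in df.columns
    has_items = all(c in df.columns for c in ("mo", "sc", "ua", "pd", "ad"))
    if require_outcome and not (has_index or has_items):
        raise ValueError("dataset needs eq5d_index or item columns mo,sc,ua,pd,ad")
    check = required + (["eq5d_index"] if has_index and require_outcome else []) \
        + (["mo", "sc", "ua", "pd", "ad"] if (has_items and not has_index and require_outcome) else [])
    n0 = len(df)
    df = df.dropna(subset=check).copy()
    if len(df) < n0 and logger is not None:
        logger.info("dropped %d of %d records with missing required fields",
                    n0 - len(df), n0)
    if df["sex"].dtype == object:
        bad = set(df["sex"]) - {"male", "female"}
        if bad:
            raise ValueError(f"unrecognised sex codes: {sorted(bad)}")
    kdcs = compute_kdcs(df["symptoms"].to_numpy(), df["effects"].to_numpy(),
                        df["burden"].to_numpy())
    if "kdcs" in df.columns:
        off = np.abs(df["kdcs"].to_numpy(dtype=float) - kdcs) > 0.01
        if off.any():
            raise ValueError(
                f"{int(off.sum())} records have kdcs inconsistent with the "
                "subscale mean")
    df["kdcs"] = kdcs
    return df.reset_index(drop=True)
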