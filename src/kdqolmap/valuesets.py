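"""EQ-5D instruments and value sets.

The EQ-5D describes health on five dimensions (mobility, self-care, usual
activities, pain/discomfort, anxiety/depression) with 3 or 5 levels each; a
response pattern is a *health state*.  A value set (tariff) assigns every
health state a societal utility anchored at 1 (full health), so the observable
utility distribution has a ceiling at 1, a *truncation point* Ψ — the value of
the second-best state, with no feasible value in (Ψ, 1) — and a *floor*, the
worst state's value (possibly negative, i.e. worse than death).

Two value-set forms are supported:

* ``additive`` — ``1 − constant·1{any problem} − Σ_d decrement(d, level_d)``
  with level-1 decrements equal to zero.  This is the dominant published
  parameterisation; interaction terms (e.g. worst-state bonuses) need the
  table form.
* ``table`` — an explicit map from every state to its value.

States are enumerated in lexicographic order of the five-level code, first
dimension slowest-varying: (1,1,1,1,1) first, (L,L,L,L,L) last.  Every
state-probability vector in this package uses that order.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "DIMENSIONS",
    "EQ5DProfile",
    "ValueSet",
    "enumerate_states",
    "toy_3l",
    "toy_5l",
]

DIMENSIONS = ("mobility", "self_care", "usual_activities", "pain_discomfort",
              "anxiety_depression")

_LEVELS = {"3L": 3, "5L": 5}


def _check_version(version: str) -> int:
    try:
        return _LEVELS[version]
    except KeyError:
        raise ValueError(f"unknown EQ-5D version {version!r}; expected '3L' or '5L'")


@dataclass(frozen=True)
class EQ5DProfile:
    """One EQ-5D response pattern (health state).

    Parameters
    ----------
    version : {"3L", "5L"}
    levels : tuple of 5 ints
        One level per dimension, each in ``[1, L]``.  ``(1, 1, 1, 1, 1)`` is
        full health.
    """

    version: str
    levels: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        L = _check_version(self.version)
        levels = tuple(int(v) for v in self.levels)
        if len(levels) != 5:
            raise ValueError(f"expected 5 levels, got {len(levels)}")
        for d, lev in zip(DIMENSIONS, levels):
            if not 1 <= lev <= L:
                raise ValueError(f"{d} level {lev} outside [1, {L}]")
        object.__setattr__(self, "levels", levels)

    @property
    def is_full_health(self) -> bool:
        return all(v == 1 for v in self.levels)

    @property
    def code(self) -> str:
        """Conventional five-digit state code, e.g. ``'21321'``."""
        return "".join(str(v) for v in self.levels)

    @classmethod
    def from_code(cls, version: str, code: str) -> "EQ5DProfile":
        if len(code) != 5 or not code.isdigit():
            raise ValueError(f"bad state code {code!r}")
        return cls(version, tuple(int(c) for c in code))


def enumerate_states(version: str) -> list[EQ5DProfile]:
    """All 3^5 = 243 or 5^5 = 3125 health states, lexicographic order."""
    L = _check_version(version)
    return [EQ5DProfile(version, lv)
            for lv in itertools.product(range(1, L + 1), repeat=5)]


@dataclass
class ValueSet:
    """A value set mapping every health state of one EQ-5D version to a utility.

    Derived quantities (all cached on first access):

    * ``ceiling`` — always 1 (full health anchor),
    * ``truncation_point`` (Ψ) — the maximum value over states other than full
      health; no state value lies in the open interval (Ψ, 1),
    * ``floor`` — the minimum value over all states.
    """

    name: str
    version: str
    form: str = "additive"
    constant: float = 0.0
    decrements: Mapping[str, Sequence[float]] | None = None
    table: Mapping[str, float] | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        L = _check_version(self.version)
        if self.form == "additive":
            if self.decrements is None:
                raise ValueError("additive form requires decrements")
            if self.constant < 0:
                raise ValueError("any-problem constant must be >= 0")
            dec = {}
            for d in DIMENSIONS:
                if d not in self.decrements:
                    raise ValueError(f"missing decrements for dimension {d!r}")
                vals = [float(v) for v in self.decrements[d]]
                if len(vals) != L - 1:
                    raise ValueError(
                        f"dimension {d!r}: expected {L - 1} decrements "
                        f"(levels 2..{L}), got {len(vals)}")
                dec[d] = tuple(vals)
            self.decrements = dec
        elif self.form == "table":
            if self.table is None:
                raise ValueError("table form requires a state->value table")
            expected = {s.code for s in enumerate_states(self.version)}
            got = set(self.table)
            if got != expected:
                missing = sorted(expected - got)[:5]
                extra = sorted(got - expected)[:5]
                raise ValueError(
                    f"table must cover all {len(expected)} states; "
                    f"missing e.g. {missing}, unexpected e.g. {extra}")
            if abs(self.table["11111"] - 1.0) > 1e-12:
                raise ValueError("full health (11111) must have value 1")
            self.table = {k: float(v) for k, v in self.table.items()}
        else:
            raise ValueError(f"unknown form {self.form!r}")

    # -- index computation ---------------------------------------------------

    def index_of(self, profile: EQ5DProfile) -> float:
        """Utility index of one health state under this value set."""
        if profile.version != self.version:
            raise ValueError(
                f"profile version {profile.version} does not match "
                f"value set version {self.version}")
        if self.form == "table":
            return self.table[profile.code]
        if profile.is_full_health:
            return 1.0
        total = self.constant
        for d, lev in zip(DIMENSIONS, profile.levels):
            if lev > 1:
                total += self.decrements[d][lev - 2]
        return 1.0 - total

    def index_of_levels(self, levels) -> float:
        return self.index_of(EQ5DProfile(self.version, tuple(levels)))

    def all_values(self) -> list[float]:
        """Index values of all states, in enumeration order (cached)."""
        if "values" not in self._cache:
            self._cache["values"] = [self.index_of(s)
                                     for s in enumerate_states(self.version)]
        return self._cache["values"]

    @property
    def ceiling(self) -> float:
        return 1.0

    @property
    def truncation_point(self) -> float:
        """Ψ: highest index value strictly below full health (second-best state)."""
        if "psi" not in self._cache:
            vals = [v for s, v in zip(enumerate_states(self.version),
                                      self.all_values())
                    if not s.is_full_health]
            self._cache["psi"] = max(vals)
        return self._cache["psi"]

    @property
    def floor(self) -> float:
        """Worst-state index value (minimum over all states)."""
        if "floor" not in self._cache:
            self._cache["floor"] = min(self.all_values())
        return self._cache["floor"]

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        out = {"name": self.name, "version": self.version, "form": self.form}
        if self.form == "additive":
            out["constant"] = self.constant
            out["decrements"] = {d: list(v) for d, v in self.decrements.items()}
        else:
            out["table"] = dict(self.table)
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "ValueSet":
        return cls(name=d["name"], version=d["version"],
                   form=d.get("form", "additive"),
                   constant=float(d.get("constant", 0.0)),
                   decrements=d.get("decrements"),
                   table=d.get("table"))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "ValueSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


# -- bundled synthetic toy fixtures -------------------------------------------
# These are clearly-labelled SYNTHETIC tariffs for testing and simulation; they
# are not any country's published value set.

def toy_3l() -> ValueSet:
    """Synthetic 3L tariff "TOY3L" (floor −0.50, truncation point 0.85)."""
    return ValueSet(
        name="TOY3L", version="3L", form="additive", constant=0.10,
        decrements={
            "mobility": (0.05, 0.30),
            "self_care": (0.05, 0.25),
            "usual_activities": (0.05, 0.20),
            "pain_discomfort": (0.08, 0.35),
            "anxiety_depression": (0.07, 0.30),
        })


def toy_5l() -> ValueSet:
    """Synthetic 5L tariff "TOY5L" (finer grid, mildly negative floor)."""
    return ValueSet(
        name="TOY5L", version="5L", form="additive", constant=0.04,
        decrements={
            "mobility": (0.04, 0.08, 0.16, 0.27),
            "self_care": (0.03, 0.07, 0.14, 0.22),
            "usual_activities": (0.03, 0.06, 0.12, 0.19),
            "pain_discomfort": (0.05, 0.10, 0.19, 0.30),
            "anxiety_depression": (0.04, 0.09, 0.17, 0.26),
        })
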