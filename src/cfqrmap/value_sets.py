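"""EQ-5D-3L descriptive system and value-set (tariff) scoring.

The EQ-5D-3L describes health on five dimensions — mobility, self-care,
usual activity, pain/discomfort and anxiety/depression — each at one of
three levels (1 = no problems, 3 = extreme problems), giving 243 distinct
states.  A country-specific *value set* converts a state into a utility on a
scale anchored at 1 (full health) and 0 (dead), with negative values for
states valued worse than dead.

Only the UK general-population time-trade-off value set ships with the
package; its scoring rule is::

    U(state) = 1                                  if state == 11111
    U(state) = 1 - c - sum(decrements) - n3*[any level 3]   otherwise

where ``c`` is a constant applied for any departure from full health and
``n3`` an extra constant applied once if any dimension is at level 3.  The
UK set spans [-0.594, 1].  Other tariffs with the same functional form can
be supplied as YAML files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DIMENSIONS",
    "EQ5DState",
    "ValueSet",
    "InvalidStateError",
    "load_value_set",
    "score_eq5d_state",
    "utility_bounds",
    "enumerate_states",
    "score_table",
]

#: Canonical dimension order used everywhere (state strings, tables, tariffs).
DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activity",
    "pain_discomfort",
    "anxiety_depression",
)


class InvalidStateError(ValueError):
    """An EQ-5D level outside {1, 2, 3}; the message names the dimension."""


@dataclass(frozen=True)
class EQ5DState:
    """One EQ-5D-3L descriptive-system response (five ordinal levels)."""

    mobility: int
    self_care: int
    usual_activity: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in (1, 2, 3):
                raise InvalidStateError(
                    f"level for dimension {dim!r} must be 1, 2 or 3; got {level!r}"
                )

    @classmethod
    def from_string(cls, digits: str) -> "EQ5DState":
        """Parse a 5-digit state string such as ``"21132"``."""
        digits = str(digits).strip()
        if len(digits) != 5 or not digits.isdigit():
            raise InvalidStateError(
                f"state string must be 5 digits, e.g. '21132'; got {digits!r}"
            )
        return cls(*(int(d) for d in digits))

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, dim) for dim in DIMENSIONS)

    def __str__(self) -> str:
        return "".join(str(l) for l in self.levels)


@dataclass(frozen=True)
class ValueSet:
    """A tariff: per-dimension decrements plus the two shared constants."""

    id: str
    name: str
    constant: float            # any move away from 11111
    n3: float                  # any dimension at level 3
    decrements: dict           # dim -> {2: d2, 3: d3}
    full_health: float = 1.0

    def score(self, state: EQ5DState) -> float:
        return score_eq5d_state(state, self)

    @property
    def min_utility(self) -> float:
        return utility_bounds(self)[0]


def score_eq5d_state(state: EQ5DState | str, value_set: ValueSet) -> float:
    """Score one EQ-5D-3L state to a utility.

    Full health (11111) scores exactly ``full_health`` (1.0 for the UK set);
    any other state subtracts the constant, the per-dimension level
    decrements, and the N3 constant if any dimension is at level 3.
    """
    if not isinstance(state, EQ5DState):
        state = EQ5DState.from_string(state)
    levels = state.levels
    if all(l == 1 for l in levels):
        return value_set.full_health
    u = value_set.full_health - value_set.constant
    for dim, level in zip(DIMENSIONS, levels):
        if level > 1:
            u -= value_set.decrements[dim][level]
    if any(l == 3 for l in levels):
        u -= value_set.n3
    return u


def enumerate_states() -> list[EQ5DState]:
    """All 243 EQ-5D-3L states in lexicographic order."""
    return [EQ5DState(*lv) for lv in itertools.product((1, 2, 3), repeat=5)]


def utility_bounds(value_set: ValueSet) -> tuple[float, float]:
    """(min, max) attainable utility, by exhaustive enumeration.

    For any tariff with non-negative decrements this equals
    (score of 33333, full_health), but the bound is computed by brute force
    over all 243 states so it is correct for arbitrary decrement signs.
    """
    scores = [score_eq5d_state(s, value_set) for s in enumerate_states()]
    return min(scores), max(scores)


def load_value_set(source: str | Path = "uk_tto") -> ValueSet:
    """Load a value set from a bundled id (``"uk_tto"``) or a YAML path.

    The UK set is validated at load against its two published anchors:
    score(11111) = 1.0 and score(33333) = -0.594.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).suffix in (".yaml", ".yml"):
        text = Path(source).read_text()
    else:
        text = (resources.files("cfqrmap.data") / f"{source}.yaml").read_text()
    raw = yaml.safe_load(text)
    vs = ValueSet(
        id=raw["id"],
        name=raw["name"],
        constant=float(raw["constant"]),
        n3=float(raw["n3"]),
        decrements={d: {int(k): float(v) for k, v in levels.items()}
                    for d, levels in raw["decrements"].items()},
        full_health=float(raw.get("full_health", 1.0)),
    )
    missing = set(DIMENSIONS) - set(vs.decrements)
    if missing:
        raise ValueError(f"value set {vs.id!r} missing dimensions: {sorted(missing)}")
    if vs.id == "uk_tto":
        lo, hi = utility_bounds(vs)
        if abs(hi - 1.0) > 1e-12 or abs(lo - (-0.594)) > 1e-12:
            raise ValueError(
                f"UK value set failed anchor validation: bounds ({lo}, {hi}) "
                "instead of (-0.594, 1.0)"
            )
    return vs


def score_table(
    table: pd.DataFrame,
    value_set: ValueSet,
    state_column: str = "eq5d_state",
) -> pd.Series:
    """Score a respondent table to utilities.

    Accepts either a 5-digit state-string column (``state_column``) or the
    five per-dimension integer columns named as in :data:`DIMENSIONS`.
    """
    if state_column in table.columns:
        states = table[state_column].map(EQ5DState.from_string)
    elif all(d in table.columns for d in DIMENSIONS):
        states = table.apply(
            lambda r: EQ5DState(*(int(r[d]) for d in DIMENSIONS)), axis=1
        )
    else:
        raise KeyError(
            f"table needs either a {state_column!r} column or the five "
            f"dimension columns {DIMENSIONS}"
        )
    return states.map(lambda s: score_eq5d_state(s, value_set)).rename("utility")
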