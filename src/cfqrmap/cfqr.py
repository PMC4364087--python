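"""CFQ-R (teen/adult) item handling and domain scoring.

The CFQ-R is a 50-item, 12-domain HRQL instrument for cystic fibrosis.
Items are ordinal 1-4; after reverse coding, 4 always means best health.
A domain score is the linear 0-100 rescale of the mean of its recoded
items, ``100 * (mean - 1) / 3`` — the unique linear map sending all-1s to 0
and all-4s to 100.  Missing items are dropped from the mean; by default a
domain is scored only when at least half of its items were answered (the
common half-scale convention, declared as an assumption and configurable).

For regression modelling, the Health-perceptions domain (and its items) and
item 43 (a conditional sub-question) are excluded: the remaining items all
measure health, so the Health domain would be redundant or collinear.
Scoring itself always reports all 12 domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CFQRItemMeta",
    "ItemMap",
    "InvalidResponseError",
    "load_item_map",
    "reverse_code",
    "recode_items",
    "score_domain",
    "score_items",
    "score_record",
    "DOMAIN_ORDER",
    "MODELLING_DOMAINS",
    "EXCLUDED_DOMAIN",
]

#: Canonical domain keys, in instrument order.
DOMAIN_ORDER = (
    "physical", "role", "vitality", "emotion", "social", "body",
    "eat", "treat", "health", "weight", "respiratory", "digest",
)

#: Domain excluded from all regression models.
EXCLUDED_DOMAIN = "health"

#: The 11 domains eligible as model predictors.
MODELLING_DOMAINS = tuple(d for d in DOMAIN_ORDER if d != EXCLUDED_DOMAIN)


class InvalidResponseError(ValueError):
    """An item response outside {1, 2, 3, 4}."""


@dataclass(frozen=True)
class CFQRItemMeta:
    item: int
    domain: str
    reverse: bool = False
    ordered: bool = True
    sub_question: bool = False
    label: str = ""


@dataclass
class ItemMap:
    """Item metadata for the full instrument, with modelling views."""

    items: dict[int, CFQRItemMeta]
    domain_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        domains = {m.domain for m in self.items.values()}
        unknown = domains - set(DOMAIN_ORDER)
        if unknown:
            raise ValueError(f"unknown domains in item map: {sorted(unknown)}")

    def domain_items(self, domain: str) -> list[int]:
        return [i for i, m in sorted(self.items.items()) if m.domain == domain]

    @property
    def eligible_items(self) -> list[int]:
        """Items usable as model predictors: the Health-domain items and
        the sub-question item 43 are excluded (46 under the default map)."""
        return [
            i for i, m in sorted(self.items.items())
            if m.domain != EXCLUDED_DOMAIN and not m.sub_question
        ]

    def meta(self, item: int) -> CFQRItemMeta:
        try:
            return self.items[item]
        except KeyError:
            raise KeyError(f"unknown CFQ-R item id {item!r}") from None


def load_item_map(source: str | Path | None = None) -> ItemMap:
    """Load the item map from the bundled default or a user YAML file."""
    if source is None:
        text = (resources.files("cfqrmap.data") / "cfqr_items.yaml").read_text()
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)
    items = {
        int(i): CFQRItemMeta(
            item=int(i),
            domain=spec["domain"],
            reverse=bool(spec.get("reverse", False)),
            ordered=bool(spec.get("ordered", True)),
            sub_question=bool(spec.get("sub_question", False)),
            label=spec.get("label", ""),
        )
        for i, spec in raw["items"].items()
    }
    labels = {d: v.get("label", d) for d, v in raw.get("domains", {}).items()}
    return ItemMap(items=items, domain_labels=labels)


def reverse_code(response, flag: bool):
    """Recode one response: flagged items map r -> 5 - r, others unchanged.

    An involution on {1,2,3,4}; accepts scalars or arrays, propagates NaN.
    """
    arr = np.asarray(response, dtype=float)
    valid = np.isnan(arr) | np.isin(arr, (1, 2, 3, 4))
    if not valid.all():
        bad = np.asarray(arr)[~valid]
        raise InvalidResponseError(
            f"item responses must be in {{1,2,3,4}} or missing; got {bad[:5]}"
        )
    out = 5.0 - arr if flag else arr
    if np.isscalar(response) or np.ndim(response) == 0:
        return float(out) if np.isnan(out) else int(out)
    return out


def recode_items(items_df: pd.DataFrame, item_map: ItemMap) -> pd.DataFrame:
    """Reverse-code a table of raw item columns ``item_1`` .. ``item_50``."""
    out = items_df.copy()
    for col in out.columns:
        iid = _item_id(col)
        if iid is None:
            continue
        meta = item_map.meta(iid)
        out[col] = reverse_code(out[col].to_numpy(dtype=float), meta.reverse)
    return out


def _item_id(col: str) -> int | None:
    if isinstance(col, str) and col.startswith("item_"):
        return int(col.split("_", 1)[1])
    return None


def score_domain(responses, min_answered_frac: float = 0.5) -> float:
    """Score one domain from its *recoded* responses.

    Returns ``100 * (mean - 1) / 3`` over the non-missing responses, or NaN
    when fewer than ``min_answered_frac`` of the items were answered.
    """
    arr = np.asarray(responses, dtype=float)
    if arr.size == 0:
        return float("nan")
    bad = ~(np.isnan(arr) | np.isin(arr, (1, 2, 3, 4)))
    if bad.any():
        raise InvalidResponseError(
            f"recoded responses must be in {{1,2,3,4}} or missing; got {arr[bad][:5]}"
        )
    answered = ~np.isnan(arr)
    if answered.sum() < min_answered_frac * arr.size:
        return float("nan")
    return float(100.0 * (arr[answered].mean() - 1.0) / 3.0)


def score_items(
    items_df: pd.DataFrame,
    item_map: ItemMap | None = None,
    min_answered_frac: float = 0.5,
    recoded: bool = False,
) -> pd.DataFrame:
    """Score a table of item responses to the 12 domain scores.

    Parameters
    ----------
    items_df
        Columns ``item_1`` .. ``item_50`` (missing columns allowed; they
        count as unanswered items of their domain).
    recoded
        Set True if the responses are already reverse-coded.

    Returns a DataFrame with one 0-100 column per domain (NaN where the
    half-scale rule fails), indexed like the input.
    """
    item_map = item_map or load_item_map()
    df = items_df if recoded else recode_items(items_df, item_map)
    out = {}
    for domain in DOMAIN_ORDER:
        ids = item_map.domain_items(domain)
        if not ids:
            continue
        cols = [f"item_{i}" for i in ids]
        block = pd.DataFrame(
            {c: (df[c] if c in df.columns else np.nan) for c in cols},
            index=df.index, dtype=float,
        )
        out[domain] = block.apply(
            lambda row: score_domain(row.to_numpy(), min_answered_frac), axis=1
        )
    return pd.DataFrame(out, index=df.index)


def score_record(
    responses: dict[int, int | None],
    item_map: ItemMap | None = None,
    min_answered_frac: float = 0.5,
) -> dict:
    """Score a single respondent given ``{item id: raw response}``.

    Returns ``{"domains": {domain: score}, "modelling_domains": {...}}``
    where the modelling view omits the Health-perceptions domain.
    """
    item_map = item_map or load_item_map()
    unknown = set(responses) - set(item_map.items)
    if unknown:
        raise KeyError(f"unknown CFQ-R item ids: {sorted(unknown)}")
    row = {
        f"item_{i}": (np.nan if v is None else v) for i, v in responses.items()
    }
    frame = pd.DataFrame([row])
    scores = score_items(frame, item_map, min_answered_frac).iloc[0]
    domains = {d: float(scores[d]) for d in scores.index}
    return {
        "domains": domains,
        "modelling_domains": {d: v for d, v in domains.items()
                              if d != EXCLUDED_DOMAIN},
    }
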