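"""Apply the published domain-level mapping functions to new CFQ-R data.

This is the headline user-facing feature: given CFQ-R domain scores for
Physical, Role, Emotion, Vitality, Eat, Weight and Digest (0-100), predict
the EQ-5D-3L utility with the recommended Model 3 coefficients — either the
OLS function or the two-part function (ceiling logit combined with a
truncated regression by the expected-value rule).

Coefficients live in a bundled, provenance-annotated data file at full
printed precision; they are validated at load against the two printed
intercept anchors (-0.09898 for OLS, -0.22122 for the two-part part 2).
The part-1 intercept of the two-part function was not published: the
two-part applicator raises an explicit error unless the user supplies a
value (or refits part 1 on their own data).  Printed rounding limits
reproduction of the squared terms to about 1e-4 per 100^2 score units.

Predictions are unclamped by default (the study reported OLS predictions
above 1 unclamped); ``clamp=True`` restricts output to [-0.594, 1] for use
in economic models, and the out-of-range flag is always recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit
import yaml

__all__ = [
    "PublishedCoefficients",
    "MappedUtility",
    "Part1ConstantUnavailable",
    "load_published",
    "map_ols_model3",
    "map_tpm_model3",
    "map_table",
    "DOMAIN_ALIASES",
    "REQUIRED_DOMAINS",
    "UTILITY_BOUNDS",
]

UTILITY_BOUNDS = (-0.594, 1.0)

#: The seven CFQ-R domains the Model 3 functions require (canonical keys).
REQUIRED_DOMAINS = ("physical", "role", "emotion", "vitality", "eat",
                    "weight", "digest")

#: Column-name aliases accepted for each domain (both label styles used in
#: the literature, case-insensitive after stripping).
DOMAIN_ALIASES = {
    "physical": ("physical", "physical functioning"),
    "role": ("role", "role functioning"),
    "emotion": ("emotion", "emotions", "emotional functioning"),
    "vitality": ("vitality",),
    "eat": ("eat", "eating disturbance", "eating disturbances"),
    "weight": ("weight",),
    "digest": ("digest", "digestion", "digestive symptoms"),
}

_ANCHORS = {"ols_model3": -0.09898, "tpm_model3_part2": -0.22122}


class Part1ConstantUnavailable(RuntimeError):
    """The two-part part-1 intercept was not published.

    Supply ``part1_constant`` (for example from a part-1 refit on your own
    data) to use the two-part mapping function.
    """


@dataclass(frozen=True)
class PublishedCoefficients:
    model_id: str
    coefficients: dict       # name -> float; part-1 const may be None
    se: dict
    provenance: str


@dataclass(frozen=True)
class MappedUtility:
    respondent_id: object
    prediction: float
    out_of_range: bool
    clamped: bool
    model_id: str


def load_published(model_id: str) -> PublishedCoefficients:
    """Load one published coefficient set (``ols_model3``,
    ``tpm_model3_part1`` or ``tpm_model3_part2``) with anchor validation."""
    raw = yaml.safe_load(
        (resources.files("cfqrmap.data") / "published_model3.yaml").read_text()
    )
    if model_id not in raw:
        raise KeyError(f"unknown published model {model_id!r}")
    block = raw[model_id]
    coefs = {k: (None if v is None else float(v))
             for k, v in block["coefficients"].items()}
    anchor = _ANCHORS.get(model_id)
    if anchor is not None and coefs.get("const") != anchor:
        raise ValueError(
            f"bundled coefficients for {model_id} fail the intercept anchor "
            f"check ({coefs.get('const')} != {anchor}); data file corrupted?"
        )
    return PublishedCoefficients(
        model_id=model_id,
        coefficients=coefs,
        se={k: float(v) for k, v in block.get("se", {}).items()},
        provenance=raw.get("provenance", "").strip(),
    )


def _check_domains(domains: dict) -> dict:
    vals = {}
    for d in REQUIRED_DOMAINS:
        if d not in domains or domains[d] is None or (
                isinstance(domains[d], float) and np.isnan(domains[d])):
            raise KeyError(f"missing required domain score: {d!r}")
        v = float(domains[d])
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"domain {d!r} score {v} outside [0, 100]")
        vals[d] = v
    return vals


def _linear_predictor(coefs: dict, vals: dict, const: float) -> float:
    eta = const
    for name, beta in coefs.items():
        if name == "const" or beta is None:
            continue
        if name.endswith("_sq"):
            eta += beta * vals[name[:-3]] ** 2
        else:
            eta += beta * vals[name]
    return eta


def _flagged(pred: float, clamp: bool):
    lo, hi = UTILITY_BOUNDS
    out = not (lo <= pred <= hi)
    return (min(max(pred, lo), hi) if clamp else pred), out


def map_ols_model3(domains: dict, clamp: bool = False,
                   respondent_id=None) -> MappedUtility:
    """OLS Model 3 prediction from the seven required domain scores."""
    pub = load_published("ols_model3")
    vals = _check_domains(domains)
    eta = _linear_predictor(pub.coefficients, vals, pub.coefficients["const"])
    pred, out = _flagged(eta, clamp)
    return MappedUtility(respondent_id, float(pred), out, clamp, "ols_model3")


def map_tpm_model3(domains: dict, part1_constant: float | None = None,
                   clamp: bool = False, respondent_id=None) -> MappedUtility:
    """Two-part Model 3 prediction.

    ``p`` comes from the logistic of the part-1 linear predictor (three
    domains), ``yhat2`` from the part-2 linear predictor (seven domains
    plus three squared terms); the output is ``p + (1 - p) * yhat2``.
    Raises :class:`Part1ConstantUnavailable` without ``part1_constant``.
    """
    if part1_constant is None:
        raise Part1ConstantUnavailable(
            "the published coefficient table prints no part-1 intercept "
            "(only the part-2 constant -0.22122 is given); pass "
            "part1_constant= from a refit or an assumed value"
        )
    part1 = load_published("tpm_model3_part1")
    part2 = load_published("tpm_model3_part2")
    vals = _check_domains(domains)
    eta1 = _linear_predictor(part1.coefficients, vals, float(part1_constant))
    p = float(expit(eta1))
    yhat2 = _linear_predictor(part2.coefficients, vals,
                              part2.coefficients["const"])
    ev = p * 1.0 + (1.0 - p) * yhat2
    pred, out = _flagged(float(ev), clamp)
    return MappedUtility(respondent_id, float(pred), out, clamp, "tpm_model3")


def resolve_domain_columns(columns) -> dict:
    """Map table columns onto canonical domain keys via the alias table."""
    norm = {str(c).strip().lower(): c for c in columns}
    found = {}
    for key, aliases in DOMAIN_ALIASES.items():
        for a in aliases:
            if a in norm:
                found[key] = norm[a]
                break
    return found


def map_table(table: pd.DataFrame, model_id: str = "ols_model3",
              clamp: bool = False, part1_constant: float | None = None,
              id_column: str | None = None) -> tuple[pd.DataFrame, dict]:
    """Row-wise mapping of a domain-score table.

    Rows with missing or out-of-range domains are emitted with a missing
    prediction and a reason; the summary block reports counts and the
    mean/SD of the successful predictions.

    Returns ``(output table, summary dict)``.
    """
    colmap = resolve_domain_columns(table.columns)
    if not colmap:
        raise KeyError(
            "no resolvable domain columns; expected any aliases of "
            f"{list(DOMAIN_ALIASES)}"
        )
    rows = []
    for idx, row in table.iterrows():
        rid = row[id_column] if id_column else idx
        domains = {k: row[c] for k, c in colmap.items()}
        try:
            if model_id == "ols_model3":
                m = map_ols_model3(domains, clamp, rid)
            elif model_id in ("tpm_model3", "tpm"):
                m = map_tpm_model3(domains, part1_constant, clamp, rid)
            else:
                raise KeyError(f"unknown mapping model {model_id!r}")
            rows.append({"respondent_id": rid, "prediction": m.prediction,
                         "out_of_range": m.out_of_range, "reason": ""})
        except (KeyError, ValueError) as exc:
            if isinstance(exc, KeyError) and "unknown mapping model" in str(exc):
                raise
            rows.append({"respondent_id": rid, "prediction": np.nan,
                         "out_of_range": False, "reason": str(exc)})
    out = pd.DataFrame(rows, columns=["respondent_id", "prediction",
                                      "out_of_range", "reason"])
    ok = out["prediction"].notna()
    summary = {
        "model": model_id,
        "n_mapped": int(ok.sum()),
        "n_skipped": int((~ok).sum()),
        "mean": float(out.loc[ok, "prediction"].mean()) if ok.any() else None,
        "sd": float(out.loc[ok, "prediction"].std(ddof=1)) if ok.sum() > 1 else None,
        "clamp": clamp,
    }
    return out, summary
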