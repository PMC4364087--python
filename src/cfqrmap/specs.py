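"""The eight model specifications and their data-driven resolution.

The mapping study evaluates eight predictor sets, each combined with three
estimator families (OLS, Tobit, two-part):

1. all CFQ-R domains (Health excluded)
2. domains significant at the 10% level in the full fit
3. model 2 plus significant squared terms
4. model 3 plus significant interaction terms
5. all CFQ-R items (Health items and item 43 excluded), dummy coded with
   level 1 (poor health) as the reference
6. items significant at the 10% level (kept/dropped as whole dummy blocks,
   joint Wald test)
7. model 6 with non-monotone ("unordered") items dichotomised to
   'no problems' vs 'other'
8. the best-fitting model plus age and gender

Specs themselves are pure data (:class:`ModelSpec`); resolving one against
a dataset and family (:func:`resolve_model`) performs the single-pass
screening, squared/interaction construction, unordered-item detection and
ceiling-part level collapsing, returning the fitted results together with
a :class:`DesignRecipe` that can rebuild the identical design on new data
(used by cross-validation).

For the two-part family, part 1 (ceiling logit) and part 2 (truncated
regression) are screened separately; item-level part-1 designs always use
collapsed (2-3 level) codings to keep the ceiling logit estimable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cfqr
from . import estimators as est

__all__ = [
    "ModelSpec",
    "ScreeningResult",
    "DesignRecipe",
    "ResolvedModel",
    "build_spec",
    "screen_predictors",
    "detect_unordered_items",
    "collapse_for_part1",
    "domain_design",
    "item_design",
    "resolve_model",
    "EmptyScreenError",
]

log = logging.getLogger(__name__)

SCREEN_ALPHA = 0.10
COVARIATES = ("age", "male")


class EmptyScreenError(ValueError):
    """Screening retained nothing; fall back to the unscreened model."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one of the eight specifications."""

    number: int
    level: str                    # "domain" | "item"
    screen: bool = False
    squared: bool = False
    interactions: bool = False
    collapse_unordered: bool = False
    covariates: tuple = ()
    base: int | None = None       # model 8 only: the spec it extends

    def describe(self) -> str:
        return _DESCRIPTIONS[self.number]


_DESCRIPTIONS = {
    1: "all CFQ-R domains excluding the Health domain",
    2: "CFQ-R domains significant at the 10% level",
    3: "model 2 + statistically significant squared terms",
    4: "model 3 + statistically significant interaction terms",
    5: "all CFQ-R items excluding the Health-domain items",
    6: "CFQ-R items significant at the 10% level",
    7: "model 6 with collapsed unordered items",
    8: "best fitting model + gender and age",
}


def build_spec(number: int, level_context: str | None = None,
               base: int | None = None) -> ModelSpec:
    """Return the declarative spec for model ``number`` (1-8).

    ``base`` applies to model 8 only: the specification it extends
    (default: model 5, the best-fitting item-level model).  ``level_context``
    is only consulted for model 8 and must agree with the base spec.
    """
    if number not in range(1, 9):
        raise ValueError(f"model number must be 1-8, got {number}")
    if number <= 4:
        return ModelSpec(number, "domain", screen=number >= 2,
                         squared=number >= 3, interactions=number == 4)
    if number <= 7:
        return ModelSpec(number, "item", screen=number >= 6,
                         collapse_unordered=number == 7)
    base = 5 if base is None else base
    base_spec = build_spec(base)
    if level_context and level_context != base_spec.level:
        raise ValueError(
            f"model 8 base (model {base}) is {base_spec.level}-level, "
            f"not {level_context}"
        )
    return ModelSpec(8, base_spec.level, screen=base_spec.screen,
                     squared=base_spec.squared,
                     interactions=base_spec.interactions,
                     collapse_unordered=base_spec.collapse_unordered,
                     covariates=COVARIATES, base=base)


@dataclass
class ScreeningResult:
    retained: list
    dropped: dict                 # name -> p-value
    threshold: float
    what: str = "predictors"


def screen_predictors(results, threshold: float = SCREEN_ALPHA,
                      candidates: list | None = None,
                      blocks: dict | None = None,
                      what: str = "predictors") -> ScreeningResult:
    """Single-pass screen on a fitted model's p-values.

    Plain predictors are kept when their individual p-value is below
    ``threshold``; dummy-coded item ``blocks`` ({block: [columns]}) are kept
    or dropped whole on a joint Wald test.  The caller refits on the
    retained set.
    """
    retained, dropped = [], {}
    if blocks is not None:
        for name, cols in blocks.items():
            _, p, df = results.wald_joint(list(cols))
            if df == 0:
                dropped[name] = 1.0
            elif p < threshold:
                retained.append(name)
            else:
                dropped[name] = p
    else:
        cand = list(candidates) if candidates is not None else [
            c for c in results.params.index
            if c not in ("const", "log_sigma")
        ]
        pvals = results.pvalues
        for name in cand:
            if pvals[name] < threshold:
                retained.append(name)
            else:
                dropped[name] = float(pvals[name])
    return ScreeningResult(retained, dropped, threshold, what)


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------


def domain_design(data: pd.DataFrame,
                  domains=cfqr.MODELLING_DOMAINS,
                  squared=(), interactions=(), covariates=()) -> pd.DataFrame:
    """Domain-level design matrix (0-100 scores, uncentred) with intercept.

    ``squared`` lists base domains to square (column ``{d}_sq``);
    ``interactions`` lists pairs (column ``{a}_x_{b}``).
    """
    cols = {d: data[d].astype(float) for d in domains}
    cols.update({f"{d}_sq": data[d].astype(float) ** 2 for d in squared})
    cols.update({f"{a}_x_{b}": data[a].astype(float) * data[b].astype(float)
                 for a, b in interactions})
    cols.update({c: data[c].astype(float) for c in covariates})
    cols["const"] = 1.0
    return pd.DataFrame(cols, index=data.index)


def item_design(data: pd.DataFrame, item_ids,
                collapse_maps: dict | None = None,
                dichotomised=(), covariates=()) -> tuple[pd.DataFrame, dict]:
    """Item-level dummy design from *recoded* item columns.

    Each item contributes indicator columns ``item_{i}_l{v}`` for its
    observed levels above the lowest (the reference, poor health); empty
    levels produce no column.  ``collapse_maps`` ({item: {level: merged
    level}}) recode levels first; ``dichotomised`` items contribute a single
    'no problems' indicator ``item_{i}_nop`` (recoded level 4) instead.

    Returns (design with intercept, {item: [its dummy columns]}).
    """
    collapse_maps = collapse_maps or {}
    out: dict[str, pd.Series] = {}
    blocks: dict[int, list[str]] = {}
    for iid in item_ids:
        col = data[f"item_{iid}"].astype(float)
        if iid in dichotomised:
            name = f"item_{iid}_nop"
            out[name] = (col == 4).astype(float)
            blocks[iid] = [name]
            continue
        if iid in collapse_maps:
            col = col.map(lambda v: collapse_maps[iid].get(int(v), int(v)))
        levels = sorted(pd.unique(col.dropna()))
        cols = []
        for lv in levels[1:]:             # lowest observed level = reference
            name = f"item_{iid}_l{int(lv)}"
            out[name] = (col == lv).astype(float)
            cols.append(name)
        if not cols:
            log.warning("item %s is constant and was dropped from the design", iid)
        blocks[iid] = cols
    for c in covariates:
        out[c] = data[c].astype(float)
    out["const"] = 1.0
    return pd.DataFrame(out, index=data.index), blocks


def detect_unordered_items(results, blocks: dict) -> pd.DataFrame:
    """Monotonicity verdicts for dummy-coded items.

    An item is *ordered* when its level coefficients (relative to the
    poor-health reference) are monotone non-decreasing toward better
    health; anything else is flagged unordered and should be dichotomised.
    Items contributing fewer than two observed non-reference levels cannot
    be assessed and are marked ``insufficient``.
    """
    rows = []
    for iid, cols in blocks.items():
        cols = [c for c in cols if c in results.params.index]
        if len(cols) < 2:
            rows.append({"item": iid, "verdict": "insufficient",
                         "coefficients": tuple()})
            continue
        coefs = results.params[cols].to_numpy()
        verdict = "ordered" if np.all(np.diff(coefs) >= 0) else "unordered"
        rows.append({"item": iid, "verdict": verdict,
                     "coefficients": tuple(coefs)})
    return pd.DataFrame(rows).set_index("item")


def collapse_for_part1(data: pd.DataFrame, ceiling: pd.Series,
                       item_ids=None, min_count: int = 1,
                       max_levels: int = 3) -> dict:
    """Level-collapse maps for the ceiling-logit part of item models.

    Per item, any level whose cell count in either outcome class falls
    below ``min_count`` is merged with the adjacent level toward worse
    health (i.e. downward); the result is then capped at ``max_levels`` by
    merging the worst levels.  Items left with a single level are dropped
    (the caller's design builder emits no column for them).

    Returns {item: {original level: collapsed level}}.
    """
    item_ids = list(item_ids) if item_ids is not None else [
        int(c.split("_")[1]) for c in data.columns if c.startswith("item_")
    ]
    z = np.asarray(ceiling, dtype=bool)
    maps: dict[int, dict[int, int]] = {}
    for iid in item_ids:
        col = data[f"item_{iid}"].astype(float).to_numpy()
        levels = sorted(int(v) for v in np.unique(col[~np.isnan(col)]))
        groups = [[lv] for lv in levels]

        def counts(group):
            mask = np.isin(col, group)
            return (mask & z).sum(), (mask & ~z).sum()

        changed = True
        while changed and len(groups) > 1:
            changed = False
            for gi, group in enumerate(groups):
                c1, c0 = counts(group)
                if c1 < min_count or c0 < min_count:
                    tgt = gi - 1 if gi > 0 else gi + 1   # toward worse health
                    groups[tgt] = groups[tgt] + group
                    del groups[gi]
                    changed = True
                    break
        while len(groups) > max_levels:
            groups[0] = groups[0] + groups[1]            # merge the two worst
            del groups[1]
        mapping = {}
        for group in groups:
            rep = min(group)
            for lv in group:
                mapping[lv] = rep
        maps[iid] = mapping
        if len(groups) == 1:
            log.warning("item %s constant within an outcome class; it will "
                        "be dropped from the part-1 design", iid)
    return maps


@dataclass
class DesignRecipe:
    """Frozen instructions to rebuild a resolved design on new data."""

    level: str
    columns: list                          # final design columns, incl const
    domains: tuple = ()
    squared: tuple = ()
    interactions: tuple = ()
    covariates: tuple = ()
    item_ids: tuple = ()
    collapse_maps: dict = field(default_factory=dict)
    dichotomised: tuple = ()

    def build(self, data: pd.DataFrame) -> pd.DataFrame:
        if self.level == "domain":
            X = domain_design(data, self.domains, self.squared,
                              self.interactions, self.covariates)
        else:
            X, _ = item_design(data, self.item_ids, self.collapse_maps,
                               self.dichotomised, self.covariates)
        # align to the fitted columns: unseen dummies appear as zeros
        return X.reindex(columns=self.columns, fill_value=0.0)


@dataclass
class ResolvedModel:
    """A spec resolved against data: fitted results + reproducible design."""

    spec: ModelSpec
    family: str
    results: object                         # MappingResults | TwoPartResults
    recipe: DesignRecipe                    # part-2/single-part recipe
    recipe_part1: DesignRecipe | None = None
    screening: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def predict(self, data: pd.DataFrame, **kw) -> pd.Series:
        if self.family == "tpm":
            return self.results.predict(self.recipe_part1.build(data),
                                        self.recipe.build(data), **kw)
        return self.results.predict(self.recipe.build(data), **kw)


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------


def _fit(family: str, X: pd.DataFrame, y, upper: float = 1.0,
         bounds=est.DEFAULT_TRUNC_BOUNDS):
    if family == "ols":
        return est.fit_ols(X, y)
    if family == "tobit":
        return est.fit_tobit(X, y, upper=upper)
    if family == "logit":
        return est.fit_logit(X, y)
    if family == "truncated":
        return est.fit_truncated(X, y, bounds=bounds)
    raise ValueError(f"unknown family {family!r}")


def _resolve_domain_single(spec, data, y, family, alpha, covariates, notes,
                           screening, bounds):
    domains = list(cfqr.MODELLING_DOMAINS)
    X = domain_design(data, domains, covariates=covariates)
    res = _fit(family, X, y, bounds=bounds)
    squared, interactions = (), ()
    if spec.screen:
        scr = screen_predictors(res, alpha, candidates=domains, what="domains")
        screening.append(scr)
        if not scr.retained:
            raise EmptyScreenError(
                "no domain significant at the "
                f"{alpha:.0%} level; use model 1 instead"
            )
        domains = scr.retained
    if spec.squared:
        cand_sq = tuple(domains)
        X = domain_design(data, domains, squared=cand_sq, covariates=covariates)
        res_full = _fit(family, X, y, bounds=bounds)
        scr = screen_predictors(res_full, alpha,
                                candidates=[f"{d}_sq" for d in cand_sq],
                                what="squared terms")
        screening.append(scr)
        squared = tuple(s[:-3] for s in scr.retained)
    if spec.interactions:
        pairs = [(a, b) for i, a in enumerate(domains) for b in domains[i + 1:]]
        if not pairs:
            notes.append("fewer than two retained domains: no interaction "
                         "candidates")
            log.info("model %d: no interaction pairs available", spec.number)
        else:
            X = domain_design(data, domains, squared=squared,
                              interactions=pairs, covariates=covariates)
            res_full = _fit(family, X, y, bounds=bounds)
            scr = screen_predictors(
                res_full, alpha,
                candidates=[f"{a}_x_{b}" for a, b in pairs],
                what="interaction terms")
            screening.append(scr)
            interactions = tuple((a.split("_x_")[0], a.split("_x_")[1])
                                 for a in scr.retained)
    X = domain_design(data, domains, squared=squared,
                      interactions=interactions, covariates=covariates)
    res = _fit(family, X, y, bounds=bounds)
    recipe = DesignRecipe("domain", list(X.columns), tuple(domains),
                          squared, interactions, tuple(covariates))
    return res, recipe


def _resolve_item_single(spec, data, y, family, alpha, covariates, notes,
                         screening, bounds, item_map, collapse_maps=None):
    ids = list(item_map.eligible_items)
    X, blocks = item_design(data, ids, collapse_maps, covariates=covariates)
    res = _fit(family, X, y, bounds=bounds)
    dichotomised: tuple = ()
    if spec.screen:
        scr = screen_predictors(res, alpha, blocks=blocks, what="item blocks")
        screening.append(scr)
        if not scr.retained:
            raise EmptyScreenError(
                f"no item block significant at the {alpha:.0%} level; "
                "use model 5 instead")
        ids = scr.retained
        X, blocks = item_design(data, ids, collapse_maps,
                                covariates=covariates)
        res = _fit(family, X, y, bounds=bounds)
    if spec.collapse_unordered:
        verdicts = detect_unordered_items(res, blocks)
        dichotomised = tuple(
            verdicts.index[verdicts["verdict"] == "unordered"])
        notes.append(f"dichotomised {len(dichotomised)} unordered items")
        X, blocks = item_design(data, ids, collapse_maps, dichotomised,
                                covariates=covariates)
        res = _fit(family, X, y, bounds=bounds)
    recipe = DesignRecipe("item", list(X.columns), covariates=tuple(covariates),
                          item_ids=tuple(ids),
                          collapse_maps=collapse_maps or {},
                          dichotomised=dichotomised)
    return res, recipe


def resolve_model(spec: ModelSpec | int, data: pd.DataFrame,
                  family: str, alpha: float = SCREEN_ALPHA,
                  item_map: cfqr.ItemMap | None = None,
                  utility_col: str = "utility",
                  bounds=est.DEFAULT_TRUNC_BOUNDS,
                  part1_min_count: int = 5) -> ResolvedModel:
    """Resolve and fit one specification against a dataset.

    ``data`` must carry the utility column, the 11 modelling-domain scores
    and (for item-level specs) *recoded* item columns; model 8 additionally
    needs the covariates (age, male).  ``family`` is one of ``"ols"``,
    ``"tobit"``, ``"tpm"``.
    """
    if isinstance(spec, int):
        spec = build_spec(spec)
    item_map = item_map or cfqr.load_item_map()
    y = data[utility_col].astype(float)
    screening: list = []
    notes: list = []
    covariates = spec.covariates

    if family in ("ols", "tobit"):
        if spec.level == "domain":
            res, recipe = _resolve_domain_single(
                spec, data, y, family, alpha, covariates, notes, screening,
                bounds)
        else:
            res, recipe = _resolve_item_single(
                spec, data, y, family, alpha, covariates, notes, screening,
                bounds, item_map)
        return ResolvedModel(spec, family, res, recipe, None, screening, notes)

    if family != "tpm":
        raise ValueError(f"unknown family {family!r}")

    # two-part: screen each part on its own outcome
    ceiling = np.isclose(y.to_numpy(), 1.0, rtol=0, atol=1e-12)
    z = pd.Series(ceiling.astype(float), index=data.index)
    sub = data.loc[~ceiling]
    y2 = y[~ceiling]

    if spec.level == "domain":
        res1, recipe1 = _resolve_domain_single(
            spec, data, z, "logit", alpha, covariates, notes, screening,
            bounds)
        res2, recipe2 = _resolve_domain_single(
            spec, sub, y2, "truncated", alpha, covariates, notes, screening,
            bounds)
    else:
        cmaps = collapse_for_part1(data, z, item_map.eligible_items,
                                   min_count=part1_min_count)
        notes.append("part-1 item levels collapsed for the ceiling logit")
        res1, recipe1 = _resolve_item_single(
            spec, data, z, "logit", alpha, covariates, notes, screening,
            bounds, item_map, collapse_maps=cmaps)
        res2, recipe2 = _resolve_item_single(
            spec, sub, y2, "truncated", alpha, covariates, notes, screening,
            bounds, item_map)

    model = est.TwoPartMapper(y, recipe1.build(data), recipe2.build(data),
                              bounds=bounds)
    results = est.TwoPartResults(model, res1, res2)
    return ResolvedModel(spec, family, results, recipe2, recipe1,
                         screening, notes)
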