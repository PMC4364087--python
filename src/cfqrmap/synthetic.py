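"""Synthetic respondent cohorts for the CFQ-R -> EQ-5D mapping problem.

No respondent-level dataset is publicly deposited for this mapping problem,
so the package ships a generator that emulates the *statistical structure*
the mapping study assumes:

* one latent health trait per respondent (plus small domain-specific
  noise) drives both instruments, giving the CFQ-R <-> EQ-5D dependence a
  mapping needs;
* EQ-5D dimensions are conditionally independent ordinal probit draws
  given the trait, with thresholds calibrated so the scored utilities hit
  the study marginals: about 19% at the ceiling (utility exactly 1), about
  3% negative, mean about 0.67;
* CFQ-R item thresholds are calibrated per domain to the study's observed
  domain means (0-100 scale); the digestive-symptoms domain gets a
  near-zero loading so it does not track severity, mirroring the one
  domain that did not follow the severity gradient;
* demographics and lung function follow the study sample: age 28.7 +/- 8.9
  years on 18-62, 38.9% male, FEV1 %-predicted 65.7 +/- 27.3 on 17-99 with
  severity bands mild > 70, moderate 41-70, severe < 41.

Calibration is deterministic (no Monte Carlo): marginals are computed by
Gauss-Hermite quadrature over the trait combined with exact enumeration of
the 243 EQ-5D states, and three threshold parameters are solved by root
finding.  Fixed seeds give bit-identical cohorts.

``generate_linear`` is a separate plain linear-model generator (uniform
predictors, Gaussian noise, optional censoring/truncation) used for
parameter-recovery testing of the estimators against published
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.special import ndtr, roots_hermitenorm

from . import value_sets as vs
from . import cfqr

__all__ = [
    "CohortConfig",
    "LinearGenConfig",
    "CalibrationError",
    "calibrate_thresholds",
    "generate_cohort",
    "generate_linear",
    "TABLE_DOMAIN_MEANS",
]


class CalibrationError(RuntimeError):
    """Marginal targets unattainable or threshold search failed."""


#: Observed total-sample CFQ-R domain means (0-100) the item thresholds
#: are calibrated to.
TABLE_DOMAIN_MEANS = {
    "physical": 45.71, "role": 59.87, "vitality": 40.69, "emotion": 57.47,
    "social": 56.12, "body": 58.38, "eat": 74.70, "treat": 49.40,
    "health": 44.25, "weight": 60.76, "respiratory": 49.63, "digest": 71.27,
}

# Relative positions of the EQ-5D level-1/2 and level-2/3 thresholds across
# dimensions (z-scale); the calibration shifts/scales these jointly.  The
# pattern encodes that pain/discomfort and anxiety problems are the most
# prevalent and self-care problems the rarest, as in general EQ-5D data.
_BASE_C1 = {"mobility": 0.30, "self_care": 0.90, "usual_activity": 0.00,
            "pain_discomfort": -0.30, "anxiety_depression": 0.10}
_BASE_C2 = {"mobility": 2.00, "self_care": 2.40, "usual_activity": 1.70,
            "pain_discomfort": 1.50, "anxiety_depression": 1.70}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n: int = 401
    seed: int | None = None
    # latent structure
    eq5d_loading: float = 0.78      # corr(dimension latent, severity trait)
    domain_loadings: dict = field(default_factory=lambda: {
        d: (0.05 if d == "digest" else 0.65) for d in cfqr.DOMAIN_ORDER
    })
    domain_effect: float = 0.30     # shared within-domain noise loading
    item_threshold_gap: float = 0.90
    # marginal targets (study values)
    target_ceiling: float = 0.19
    target_negative: float = 0.03
    target_mean: float = 0.67
    domain_means: dict = field(default_factory=lambda: dict(TABLE_DOMAIN_MEANS))
    # demographics / clinical
    age_mean: float = 28.7
    age_sd: float = 8.88
    age_range: tuple = (18.0, 62.0)
    age_trait_loading: float = 0.15
    male_share: float = 0.389
    fev1_mean: float = 65.7
    fev1_sd: float = 27.3
    fev1_range: tuple = (17.0, 99.0)
    fev1_loading: float = 0.55
    severity_cutpoints: tuple = (41.0, 70.0)   # severe < 41 <= moderate <= 70 < mild
    value_set: str = "uk_tto"
    calibration_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name in ("target_ceiling", "target_negative", "male_share"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        lo, hi = self.severity_cutpoints
        if not lo < hi:
            raise ValueError("severity cut-points must be ordered")


@dataclass
class LinearGenConfig:
    """Plain linear-model generator for parameter-recovery tests.

    Coefficient names ending in ``_sq`` denote squared terms of the base
    predictor (``physical_sq`` -> physical**2); ``const`` is the intercept.
    Base predictors are drawn uniformly on ``ranges`` (default 0-100).
    """

    coefficients: dict
    noise_sd: float = 0.12
    n: int = 1000
    seed: int | None = None
    ranges: dict = field(default_factory=dict)
    default_range: tuple = (0.0, 100.0)
    mode: str = "none"              # none | censor | truncate
    censor_upper: float = 1.0
    trunc_bounds: tuple = (-0.594, 0.99)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.mode not in ("none", "censor", "truncate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in self.coefficients:
            if name.endswith("_sq") and name[:-3] not in self.coefficients:
                raise KeyError(
                    f"squared term {name!r} has no base predictor "
                    f"{name[:-3]!r} in the coefficient set"
                )


# ---------------------------------------------------------------------------
# EQ-5D threshold calibration (deterministic)
# ---------------------------------------------------------------------------

_QUAD_NODES = 96


def _state_utilities(value_set: vs.ValueSet) -> tuple[np.ndarray, np.ndarray]:
    states = vs.enumerate_states()
    levels = np.array([s.levels for s in states]) - 1          # (243, 5) in {0,1,2}
    utils = np.array([vs.score_eq5d_state(s, value_set) for s in states])
    return levels, utils


def _marginals(c1: np.ndarray, c2: np.ndarray, loading: float,
               levels: np.ndarray, utils: np.ndarray) -> tuple[float, float, float]:
    """(ceiling share, negative share, mean utility) by quadrature.

    Dimension latent: s_d = loading * theta + sqrt(1-loading^2) * e_d with
    theta the severity trait; level 1 iff s_d <= c1_d, level 3 iff
    s_d > c2_d.  Integrates exactly over theta ~ N(0,1) (Gauss-Hermite)
    and enumerates all 243 states.
    """
    nodes, wts = roots_hermitenorm(_QUAD_NODES)
    wts = wts / np.sqrt(2.0 * np.pi)
    resid = np.sqrt(1.0 - loading**2)
    # conditional level probabilities, shape (nodes, 3, 5)
    z1 = (c1[None, :] - loading * nodes[:, None]) / resid
    z2 = (c2[None, :] - loading * nodes[:, None]) / resid
    p1, p2c = ndtr(z1), ndtr(z2)
    P = np.stack([p1, p2c - p1, 1.0 - p2c], axis=1)
    state_p = P[:, levels, np.arange(5)].prod(axis=2)          # (nodes, 243)
    marg = wts @ state_p                                       # (243,)
    ceiling = float(marg[(levels == 0).all(axis=1)].sum())
    negative = float(marg[utils < 0].sum())
    mean = float(marg @ utils)
    return ceiling, negative, mean


def calibrate_thresholds(
    targets: tuple[float, float, float] = (0.19, 0.03, 0.67),
    loading: float = 0.78,
    value_set: str = "uk_tto",
    tol: float = 0.02,
) -> dict:
    """Solve EQ-5D ordinal thresholds for the target marginals.

    ``targets = (ceiling share, negative share, mean utility)``.  Three
    parameters — a shift of the level-1/2 thresholds, a shift of the
    level-2/3 thresholds and a common spread scale — are solved by a
    monotone-in-each-argument root search on the quadrature marginals.

    Returns ``{"c1": {dim: ...}, "c2": {...}, "achieved": (...),
    "params": (...)}``; raises :class:`CalibrationError` when the search
    does not reach the targets within ``tol``.
    """
    t_ceil, t_neg, t_mean = targets
    if t_ceil >= 1.0:
        if t_neg > 0 or abs(t_mean - 1.0) > 1e-12:
            raise CalibrationError(
                "ceiling share 1.0 forces every state to 11111; negative "
                f"share {t_neg} and mean {t_mean} are unattainable"
            )
        inf = float("inf")
        return {"c1": {d: inf for d in vs.DIMENSIONS},
                "c2": {d: inf for d in vs.DIMENSIONS},
                "achieved": (1.0, 0.0, 1.0), "params": None}
    return _calibrate_cached(round(t_ceil, 6), round(t_neg, 6),
                             round(t_mean, 6), round(loading, 6),
                             value_set, tol)


@lru_cache(maxsize=32)
def _calibrate_cached(t_ceil, t_neg, t_mean, loading, value_set, tol) -> dict:
    levels, utils = _state_utilities(vs.load_value_set(value_set))
    o1 = np.array([_BASE_C1[d] for d in vs.DIMENSIONS])
    o2 = np.array([_BASE_C2[d] for d in vs.DIMENSIONS])

    def residuals(x):
        a, b, s = x
        s = abs(s)
        c1 = a + s * o1
        c2 = np.maximum(b + s * o2, c1 + 0.05)
        got = _marginals(c1, c2, loading, levels, utils)
        return [got[0] - t_ceil, got[1] - t_neg, got[2] - t_mean]

    sol = scipy.optimize.root(residuals, x0=[0.5, 0.0, 1.0], method="hybr")
    a, b, s = sol.x
    s = abs(s)
    c1 = a + s * o1
    c2 = np.maximum(b + s * o2, c1 + 0.05)
    achieved = _marginals(c1, c2, loading, levels, utils)
    errs = (abs(achieved[0] - t_ceil), abs(achieved[1] - t_neg),
            abs(achieved[2] - t_mean))
    if max(errs) > tol:
        raise CalibrationError(
            f"threshold calibration failed for targets "
            f"({t_ceil}, {t_neg}, {t_mean}); achieved {achieved}"
        )
    return {
        "c1": dict(zip(vs.DIMENSIONS, c1)),
        "c2": dict(zip(vs.DIMENSIONS, c2)),
        "achieved": achieved,
        "params": (float(a), float(b), float(s)),
    }


# ---------------------------------------------------------------------------
# CFQ-R item thresholds
# ---------------------------------------------------------------------------


def _item_threshold(target_score: float, gap: float) -> float:
    """Centre t of item thresholds (t-gap, t, t+gap) on the N(0,1) latent
    so the expected recoded level matches a 0-100 domain-score target."""
    target_level = 1.0 + 3.0 * target_score / 100.0
    if not 1.0 < target_level < 4.0:
        raise CalibrationError(f"domain mean target {target_score} unattainable")

    def f(t):
        return (1.0 + (1 - ndtr(t - gap)) + (1 - ndtr(t)) + (1 - ndtr(t + gap))
                - target_level)

    return float(scipy.optimize.brentq(f, -8.0, 8.0))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_SCHEMA_HEAD = ["respondent_id", "age", "male", "fev1", "fev1_severity",
                "latent_trait"]


def _schema_columns(item_map: cfqr.ItemMap) -> list[str]:
    return (
        _SCHEMA_HEAD
        + [f"item_{i}" for i in sorted(item_map.items)]
        + list(cfqr.DOMAIN_ORDER)
        + list(vs.DIMENSIONS)
        + ["eq5d_state", "utility"]
    )


def generate_cohort(config: CohortConfig | None = None,
                    item_map: cfqr.ItemMap | None = None) -> pd.DataFrame:
    """Generate one respondent table under ``config``.

    Columns: demographics and lung function, raw item responses
    ``item_1..item_50`` (reverse-worded items stored on their raw polarity),
    the 12 scored domains, the five EQ-5D dimension levels, the state string
    and the scored utility.  ``latent_trait`` is the generator's health
    trait (higher = healthier), kept for structure checks.
    """
    config = config or CohortConfig()
    item_map = item_map or cfqr.load_item_map()
    cols = _schema_columns(item_map)
    if config.n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})

    value_set = vs.load_value_set(config.value_set)
    cal = calibrate_thresholds(
        (config.target_ceiling, config.target_negative, config.target_mean),
        loading=config.eq5d_loading, value_set=config.value_set,
        tol=config.calibration_tol,
    )
    c1 = np.array([cal["c1"][d] for d in vs.DIMENSIONS])
    c2 = np.array([cal["c2"][d] for d in vs.DIMENSIONS])

    rng = np.random.default_rng(config.seed)
    n = config.n

    # demographics
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n),
                  *config.age_range)
    male = (rng.random(n) < config.male_share).astype(int)
    age_z = (age - age.mean()) / age.std() if n > 1 and age.std() > 0 else np.zeros(n)

    # severity trait (higher = sicker), mildly increasing with age
    g = config.age_trait_loading
    theta = np.sqrt(max(1.0 - g**2, 0.0)) * rng.standard_normal(n) + g * age_z

    # lung function tracks the trait
    lf = config.fev1_loading
    fev1_z = -lf * theta + np.sqrt(1.0 - lf**2) * rng.standard_normal(n)
    fev1 = np.clip(config.fev1_mean + config.fev1_sd * fev1_z,
                   *config.fev1_range)
    lo_cut, hi_cut = config.severity_cutpoints
    severity = np.where(fev1 < lo_cut, "severe",
                        np.where(fev1 > hi_cut, "mild", "moderate"))

    # EQ-5D dimensions: ordinal probit given the trait
    lam = config.eq5d_loading
    resid = np.sqrt(1.0 - lam**2)
    dim_latent = lam * theta[:, None] + resid * rng.standard_normal((n, 5))
    with np.errstate(invalid="ignore"):
        dim_levels = 1 + (dim_latent > c1).astype(int) + (dim_latent > c2).astype(int)
    states = ["".join(str(l) for l in row) for row in dim_levels]
    utils = np.array([
        vs.score_eq5d_state(s, value_set) for s in states
    ])

    # CFQ-R items: shared trait + domain effect + item noise
    health = -theta
    items = {}
    kappa = config.domain_effect
    for domain in cfqr.DOMAIN_ORDER:
        ids = item_map.domain_items(domain)
        if not ids:
            continue
        rho = config.domain_loadings.get(domain, 0.65)
        resid_var = 1.0 - rho**2 - kappa**2
        if resid_var <= 0:
            raise CalibrationError(
                f"loadings for domain {domain!r} leave no item variance"
            )
        t = _item_threshold(config.domain_means[domain],
                            config.item_threshold_gap)
        gap = config.item_threshold_gap
        dom_noise = rng.standard_normal(n)
        for iid in ids:
            x = (rho * health + kappa * dom_noise
                 + np.sqrt(resid_var) * rng.standard_normal(n))
            level = 1 + (x > t - gap).astype(int) + (x > t).astype(int) \
                + (x > t + gap).astype(int)
            raw = 5 - level if item_map.meta(iid).reverse else level
            items[f"item_{iid}"] = raw

    frame = pd.DataFrame({
        "respondent_id": np.arange(1, n + 1),
        "age": age, "male": male, "fev1": fev1, "fev1_severity": severity,
        "latent_trait": health,
        **items,
    })
    domain_scores = cfqr.score_items(frame[[c for c in frame if c.startswith("item_")]],
                                     item_map)
    for d in cfqr.DOMAIN_ORDER:
        frame[d] = domain_scores[d]
    for j, d in enumerate(vs.DIMENSIONS):
        frame[d] = dim_levels[:, j]
    frame["eq5d_state"] = states
    frame["utility"] = utils
    return frame[cols]


def generate_linear(config: LinearGenConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Draw (predictor table, outcome) from an explicit linear model.

    The predictor table contains the base predictors and any derived
    squared columns; the outcome is the linear predictor plus Gaussian
    noise, optionally censored above at ``censor_upper`` or truncated (by
    resampling) to ``trunc_bounds``.
    """
    rng = np.random.default_rng(config.seed)
    base = [k for k in config.coefficients
            if k != "const" and not k.endswith("_sq")]
    sq = [k for k in config.coefficients if k.endswith("_sq")]

    def draw(m: int) -> tuple[pd.DataFrame, np.ndarray]:
        X = pd.DataFrame(index=range(m))
        for name in base:
            lo, hi = config.ranges.get(name, config.default_range)
            X[name] = rng.uniform(lo, hi, m)
        for name in sq:
            X[name] = X[name[:-3]] ** 2
        eta = np.full(m, float(config.coefficients.get("const", 0.0)))
        for name in base + sq:
            eta = eta + config.coefficients[name] * X[name].to_numpy()
        y = eta + config.noise_sd * rng.standard_normal(m)
        return X, y

    X, y = draw(config.n)
    if config.mode == "censor":
        y = np.minimum(y, config.censor_upper)
    elif config.mode == "truncate":
        lo, hi = config.trunc_bounds
        for _ in range(1000):
            bad = (y <= lo) | (y >= hi)
            if not bad.any():
                break
            Xn, yn = draw(int(bad.sum()))
            X.loc[bad, :] = Xn.to_numpy()
            y[bad] = yn
        else:
            raise CalibrationError("truncation rejection sampling did not finish")
    X.index = pd.RangeIndex(config.n)
    return X, pd.Series(y, index=X.index, name="y")
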