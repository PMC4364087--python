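"""Predictive-performance statistics, misspecification tests and
cross-validation for fitted utility mappers.

Covers the study's validation protocol: MSE/RMSE between observed and
predicted utilities, intraclass correlation (two-way random effects,
absolute agreement, single measures — the variant is a package choice, the
protocol names only "intraclass correlation"), variance inflation factors
with the >10 flag, the Ramsey RESET test (powers 2-4 of the fitted values)
for OLS, the linktest (refit on the linear predictor and its square) for
any family, subgroup tables over observed-utility bands and FEV1 severity
with one-way ANOVA, and randomised 4-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from . import estimators as est

__all__ = [
    "prediction_errors",
    "icc_agreement",
    "vif",
    "reset_test",
    "linktest",
    "subgroup_summary",
    "make_folds",
    "cross_validate",
    "ValidationReport",
    "CVResult",
    "DEFAULT_UTILITY_BANDS",
    "FEV1_BANDS",
]

log = logging.getLogger(__name__)

#: Observed-utility bands used in the study's subgroup tables.  Convention:
#: left-closed, right-open, with the last band closed at 1.
DEFAULT_UTILITY_BANDS = (-0.594, 0.1, 0.3, 0.6, 0.7, 0.8, 0.9, 1.0)

FEV1_BANDS = {"severe": (None, 41.0), "moderate": (41.0, 70.0),
              "mild": (70.0, None)}

VIF_FLAG = 10.0
MISSPEC_ALPHA = 0.05


def prediction_errors(observed, predicted) -> tuple[float, float]:
    """(MSE, RMSE) between aligned observed and predicted utilities."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0:
        raise ValueError("empty vectors")
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must be aligned")
    mse = float(np.mean((obs - pred) ** 2))
    return mse, float(np.sqrt(mse))


def icc_agreement(observed, predicted) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single measures.

    Computed from the ANOVA mean squares of the stacked n x 2 table
    (subjects x measurements).  Unlike a Pearson correlation, a constant
    shift between predictions and observations lowers the ICC.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = obs.size
    if n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    data = np.column_stack([obs, pred])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    return float((msr - mse) / denom)


def vif(X: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factors, flagging values above 10.

    The intercept column (if present) is used in the auxiliary regressions
    but not reported.  Perfectly collinear predictors give ``inf``.
    """
    X = pd.DataFrame(X).astype(float)
    cols = [c for c in X.columns if c != "const"]
    if len(cols) < 2:
        raise ValueError("VIF needs at least two predictors")
    zero_var = [c for c in cols if X[c].std() == 0]
    if zero_var:
        raise ValueError(f"constant predictors: {zero_var}")
    work = X[cols].copy()
    work["const"] = 1.0
    arr = work.to_numpy()
    rows = []
    with np.errstate(divide="ignore"):
        for j, c in enumerate(cols):
            v = float(variance_inflation_factor(arr, j))
            rows.append({"predictor": c, "vif": v, "flag": v > VIF_FLAG})
    return pd.DataFrame(rows).set_index("predictor")


def reset_test(results, powers=(2, 3, 4), alpha: float = MISSPEC_ALPHA) -> dict:
    """Ramsey RESET: F-test of powers of the fitted values in an OLS fit.

    Augments the design with fitted**p for p in ``powers`` and jointly
    tests their coefficients; ``verdict`` is "misspecified" at p < alpha.
    """
    X = results.model.exog
    y = results.model.endog
    n, k = X.shape
    if n <= k + len(powers):
        raise ValueError(
            f"n={n} too small to add {len(powers)} RESET terms to {k} columns")
    fitted = results.fittedvalues.to_numpy()
    Xa = X.copy()
    for p in powers:
        Xa[f"_fitted_pow{p}"] = fitted ** p
    if np.linalg.matrix_rank(Xa.to_numpy()) < Xa.shape[1]:
        raise ValueError("augmented RESET design is rank deficient")
    aug = sm.OLS(np.asarray(y, dtype=float), Xa.to_numpy()).fit()
    base = sm.OLS(np.asarray(y, dtype=float), X.to_numpy()).fit()
    df_num = len(powers)
    df_den = n - Xa.shape[1]
    f = ((base.ssr - aug.ssr) / df_num) / (aug.ssr / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return {"statistic": float(f), "pvalue": p, "df": (df_num, df_den),
            "verdict": "misspecified" if p < alpha else "ok"}


def linktest(results, alpha: float = MISSPEC_ALPHA) -> dict:
    """Refit the same family on {linear predictor, its square}.

    The squared term should carry no information under correct
    specification; ``verdict`` is "misspecified" when it is significant.
    Works for OLS, Tobit, truncated and logit results.
    """
    model = results.model
    xb = results.linear_predictor.to_numpy()
    if np.ptp(xb) < 1e-12:
        raise ValueError("constant linear predictor: linktest undefined")
    X = pd.DataFrame({"_hat": xb, "_hatsq": xb**2, "const": 1.0},
                     index=model.exog.index)
    family = model.family
    y = model.endog
    if family == "ols":
        refit = est.OLSMapper(y, X).fit()
    elif family == "tobit":
        refit = est.TobitMapper(y, X, upper=model.upper).fit()
    elif family == "truncated":
        refit = est.TruncatedMapper(y, X, bounds=(model.lower, model.upper)).fit()
    elif family == "logit":
        refit = est.LogitMapper(y, X).fit()
    else:
        raise ValueError(f"linktest not defined for family {family!r}")
    coef = float(refit.params["_hatsq"])
    p = float(refit.pvalues["_hatsq"])
    return {"coef": coef, "pvalue": p,
            "verdict": "misspecified" if p < alpha else "ok"}


# ---------------------------------------------------------------------------
# Subgroup tables
# ---------------------------------------------------------------------------


def _band_labels(edges) -> list[str]:
    return [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]


def subgroup_summary(observed, predicted, bands=DEFAULT_UTILITY_BANDS,
                     groups=None, spread: str = "sd") -> dict:
    """Observed/predicted summary by band (or explicit groups) plus ANOVA.

    With ``bands`` (numeric edges), observations are cut left-closed /
    right-open with the final band closed; alternatively pass ``groups``
    (labels per respondent, e.g. FEV1 severity).  ``spread`` selects what
    the per-band dispersion column reports: "sd" of the predictions or
    "rmse" against the observed values (the table labels which).
    One-way ANOVA compares predictions across non-empty bands.
    """
    obs = pd.Series(np.asarray(observed, dtype=float), name="observed")
    pred = pd.Series(np.asarray(predicted, dtype=float), name="predicted")
    if groups is not None:
        lab = pd.Series(list(groups)).astype(str)
        order = list(dict.fromkeys(lab))
    else:
        edges = list(bands)
        idx = np.clip(np.searchsorted(edges, obs.to_numpy(), side="right") - 1,
                      0, len(edges) - 2)
        labels = _band_labels(edges)
        lab = pd.Series([labels[i] for i in idx])
        order = labels
    rows = []
    groups_for_anova = []
    for g in order:
        mask = (lab == g).to_numpy()
        n = int(mask.sum())
        if n == 0:
            rows.append({"group": g, "n": 0, "observed_mean": np.nan,
                         "predicted_mean": np.nan, "spread": np.nan})
            continue
        disp = (pred[mask].std(ddof=1) if spread == "sd"
                else prediction_errors(obs[mask], pred[mask])[1])
        rows.append({"group": g, "n": n,
                     "observed_mean": float(obs[mask].mean()),
                     "predicted_mean": float(pred[mask].mean()),
                     "spread": float(disp)})
        if n >= 2:
            groups_for_anova.append(pred[mask].to_numpy())
    table = pd.DataFrame(rows).set_index("group")
    table.attrs["spread"] = spread
    if len(groups_for_anova) >= 2:
        f, p = stats.f_oneway(*groups_for_anova)
        anova = {"F": float(f), "pvalue": float(p)}
    else:
        anova = {"F": float("nan"), "pvalue": float("nan"),
                 "note": "fewer than two populated bands: ANOVA undefined"}
    return {"table": table, "anova": anova}


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Per-model validation bundle (one fitted mapper against one dataset)."""

    model_label: str
    n: int
    predicted_mean: float
    predicted_sd: float
    predicted_range: tuple
    mse: float
    rmse: float
    icc: float
    aic: object = None            # float, or (part1, part2) for two-part
    bic: object = None
    r2: float | None = None
    subgroups: dict = field(default_factory=dict)
    misspecification: dict = field(default_factory=dict)
    vif_table: pd.DataFrame | None = None

    def to_series(self) -> pd.Series:
        d = {"n": self.n, "predicted_mean": self.predicted_mean,
             "predicted_sd": self.predicted_sd,
             "predicted_min": self.predicted_range[0],
             "predicted_max": self.predicted_range[1],
             "mse": self.mse, "rmse": self.rmse, "icc": self.icc}
        for name, val in (("aic", self.aic), ("bic", self.bic)):
            if isinstance(val, tuple):
                d[f"{name}_part1"], d[f"{name}_part2"] = val
            elif val is not None:
                d[name] = val
        if self.r2 is not None:
            d["r2"] = self.r2
        return pd.Series(d, name=self.model_label)

    def render(self) -> str:
        lines = [f"Validation: {self.model_label}",
                 self.to_series().to_string()]
        for name, sub in self.subgroups.items():
            lines.append(f"\nSubgroups by {name} "
                         f"(spread = {sub['table'].attrs.get('spread')})")
            lines.append(sub["table"].to_string())
            lines.append(f"ANOVA F = {sub['anova']['F']:.2f}, "
                         f"p = {sub['anova']['pvalue']:.3g}")
        for name, t in self.misspecification.items():
            lines.append(f"{name}: p = {t['pvalue']:.3g} -> {t['verdict']}")
        return "\n".join(lines)


def validate_predictions(model_label: str, observed, predicted,
                         aic=None, bic=None, r2=None,
                         fev1_severity=None,
                         bands=DEFAULT_UTILITY_BANDS) -> ValidationReport:
    """Assemble a :class:`ValidationReport` from aligned vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    mse, rmse = prediction_errors(obs, pred)
    report = ValidationReport(
        model_label=model_label, n=len(obs),
        predicted_mean=float(pred.mean()),
        predicted_sd=float(pred.std(ddof=1)),
        predicted_range=(float(pred.min()), float(pred.max())),
        mse=mse, rmse=rmse, icc=icc_agreement(obs, pred),
        aic=aic, bic=bic, r2=r2,
    )
    report.subgroups["utility_band"] = subgroup_summary(obs, pred, bands=bands)
    if fev1_severity is not None:
        report.subgroups["fev1_severity"] = subgroup_summary(
            obs, pred, groups=fev1_severity)
    return report


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    folds: pd.Series                       # fold id per respondent
    fold_table: pd.DataFrame               # per-fold summary
    balance_anova: dict                    # observed means across folds
    seed: int | None


def make_folds(n: int, k: int = 4, seed: int | None = None) -> np.ndarray:
    """Random fold assignment partitioning ``n`` respondents into ``k``
    groups with sizes differing by at most one."""
    if n < k:
        raise ValueError(f"cannot split n={n} into {k} folds")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n, k)
    ids = np.concatenate([np.full(base + (i < extra), i, dtype=int)
                          for i in range(k)])
    rng.shuffle(ids)
    return ids


def cross_validate(data: pd.DataFrame, spec, family: str,
                   folds: int = 4, seed: int | None = None,
                   resolve_kwargs: dict | None = None) -> CVResult:
    """Randomised k-fold out-of-sample validation of one specification.

    Each fold is held out in turn; the specification is re-resolved (its
    screening re-run) and re-fitted on the remaining folds and applied to
    the held-out respondents.  The per-fold table reports n, observed and
    predicted mean/SD, predicted range, RMSE and ICC; the balance ANOVA
    compares observed means across folds (the protocol's randomisation
    check).
    """
    from .specs import resolve_model

    assign = make_folds(len(data), folds, seed)
    rows = []
    observed_by_fold = []
    for f in range(folds):
        hold = data.iloc[assign == f]
        train = data.iloc[assign != f]
        resolved = resolve_model(spec, train, family,
                                 **(resolve_kwargs or {}))
        pred = resolved.predict(hold).to_numpy()
        obs = hold["utility"].to_numpy(dtype=float)
        mse, rmse = prediction_errors(obs, pred)
        rows.append({
            "fold": f + 1, "n": len(hold),
            "observed_mean": obs.mean(), "observed_sd": obs.std(ddof=1),
            "predicted_mean": pred.mean(), "predicted_sd": pred.std(ddof=1),
            "predicted_min": pred.min(), "predicted_max": pred.max(),
            "rmse": rmse, "mse": mse, "icc": icc_agreement(obs, pred),
        })
        observed_by_fold.append(obs)
    f_stat, p = stats.f_oneway(*observed_by_fold)
    return CVResult(
        folds=pd.Series(assign, index=data.index, name="fold"),
        fold_table=pd.DataFrame(rows).set_index("fold"),
        balance_anova={"F": float(f_stat), "pvalue": float(p)},
        seed=seed,
    )
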