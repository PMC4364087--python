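"""Regression estimators for utility mapping.

Three families are provided, each as a statsmodels-style model class whose
``fit()`` returns a results object with named coefficients, standard
errors, information criteria and a ``summary()`` table:

``OLSMapper``
    Ordinary least squares (delegating to :mod:`statsmodels` internally).
``TobitMapper``
    Gaussian regression censored *above* at 1: utilities pile up at full
    health, so observed y = min(y*, 1).  Maximum likelihood, quasi-Newton
    with OLS starting values.
``TwoPartMapper``
    Part 1: logit for Pr(utility = 1).  Part 2: Gaussian regression
    truncated to the attainable non-ceiling utility interval
    (-0.594, 0.99), fitted to the sub-ceiling respondents.  Predictions
    combine the parts by the expected-value rule

        EV = P(y = 1) * 1 + (1 - P(y = 1)) * yhat_part2.

``LogitMapper`` and ``TruncatedMapper`` (the two halves) are usable on
their own.  ``bootstrap_bc`` provides bias-corrected bootstrap standard
errors and intervals for any of them.

AIC/BIC conventions: AIC = 2k - 2*llf, BIC = k*ln(n) - 2*llf.  For OLS, k
counts the regression coefficients (the statsmodels convention); for the
ML families k additionally counts the scale parameter.  Two-part criteria
are reported per part, never summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import statsmodels.api as sm
from scipy import stats
from scipy.special import log_ndtr, ndtr, ndtri
from statsmodels.tools import numdiff

__all__ = [
    "MappingResults",
    "OLSMapper",
    "TobitMapper",
    "LogitMapper",
    "TruncatedMapper",
    "TwoPartMapper",
    "TwoPartResults",
    "fit_ols",
    "fit_tobit",
    "fit_logit",
    "fit_truncated",
    "fit_two_part",
    "tpm_predict",
    "bootstrap_bc",
    "ConvergenceError",
    "CollinearityError",
    "SeparationError",
    "DataError",
]

DEFAULT_TRUNC_BOUNDS = (-0.594, 0.99)
_SQRT2PI = np.sqrt(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach the gradient tolerance."""


class CollinearityError(ValueError):
    """Rank-deficient design; the message lists the offending columns."""


class SeparationError(ValueError):
    """Perfect (or quasi-) separation in the logit part."""


class DataError(ValueError):
    """Input data violate an estimator precondition."""


def _as_design(exog) -> pd.DataFrame:
    X = pd.DataFrame(exog).copy()
    X.columns = [str(c) for c in X.columns]
    return X.astype(float)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # pivoted QR: columns beyond the numerical rank are the dependents
        _, _, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        bad = [X.columns[i] for i in piv[rank:]]
        raise CollinearityError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}"
        )



class MappingResults:
    """Fitted-mapper results: named coefficients, uncertainty, fit stats."""

    def __init__(
        self,
        model,
        params: pd.Series,
        cov: pd.DataFrame | None,
        llf: float,
        nobs: int,
        k_params: int,
        scale: float | None = None,
        extra: dict | None = None,
        use_t: bool = False,
        df_resid: float | None = None,
    ):
        self.model = model
        self.family = model.family
        self.params = params
        self.cov_params = cov
        self.llf = float(llf)
        self.nobs = int(nobs)
        self.k_params = int(k_params)
        self.scale = scale
        self.extra = extra or {}
        self.use_t = use_t
        self.df_resid = df_resid

    # -- uncertainty -------------------------------------------------------
    @property
    def bse(self) -> pd.Series:
        if self.cov_params is None:
            return pd.Series(np.nan, index=self.params.index)
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues
        if self.use_t and self.df_resid:
            return pd.Series(
                2 * stats.t.sf(np.abs(t), self.df_resid), index=t.index
            )
        return pd.Series(2 * stats.norm.sf(np.abs(t)), index=t.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.use_t and self.df_resid:
            q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        else:
            q = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def wald_joint(self, names: list[str]) -> tuple[float, float, int]:
        """Joint Wald test that the named coefficients are all zero.

        Returns (chi2 statistic, p-value, df).  Used for item-block
        screening where individual dummies must be kept or dropped together.
        """
        names = [n for n in names if n in self.params.index]
        if not names:
            return 0.0, 1.0, 0
        b = self.params[names].to_numpy()
        C = self.cov_params.loc[names, names].to_numpy()
        stat = float(b @ np.linalg.solve(C, b))
        df = len(names)
        return stat, float(stats.chi2.sf(stat, df)), df

    # -- fit statistics ----------------------------------------------------
    @property
    def aic(self) -> float:
        return 2 * self.k_params - 2 * self.llf

    @property
    def bic(self) -> float:
        return self.k_params * np.log(self.nobs) - 2 * self.llf

    # -- prediction --------------------------------------------------------
    def predict(self, exog=None, mode: str | None = None) -> pd.Series:
        X = self.model.exog if exog is None else _as_design(exog)
        return self.model._predict(self.params, X, mode)

    @property
    def fittedvalues(self) -> pd.Series:
        return self.predict()

    @property
    def linear_predictor(self) -> pd.Series:
        X = self.model.exog
        beta = self.params[X.columns]
        return pd.Series(X.to_numpy() @ beta.to_numpy(), index=X.index)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} results  (family={self.family})",
            f"n = {self.nobs}    k = {self.k_params}    "
            f"llf = {self.llf:.4f}    AIC = {self.aic:.2f}    BIC = {self.bic:.2f}",
        ]
        for key, val in self.extra.items():
            if np.isscalar(val) and isinstance(val, (int, float, np.floating)):
                lines.append(f"{key} = {val:.4f}")
        lines.append("-" * 72)
        lines.append(f"{'':<22}{'coef':>12}{'se':>12}{'z/t':>9}{'P>|z|':>9}")
        ci = self.conf_int()
        for name in self.params.index:
            lines.append(
                f"{name:<22}{self.params[name]:>12.5f}{self.bse[name]:>12.5f}"
                f"{self.tvalues[name]:>9.3f}{self.pvalues[name]:>9.4f}"
                f"   [{ci.loc[name, 'lower']:.5f}, {ci.loc[name, 'upper']:.5f}]"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Serializable description of the fitted mapper (auditable)."""
        import cfqrmap

        d = {
            "family": self.family,
            "software": f"cfqrmap {cfqrmap.__version__}",
            "n": self.nobs,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "llf": self.llf,
            "aic": float(self.aic),
            "bic": float(self.bic),
        }
        if self.scale is not None:
            d["scale"] = float(self.scale)
        d.update({k: v for k, v in self.extra.items() if np.isscalar(v)})
        return d


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------


class OLSMapper:
    """Ordinary least squares on utilities (closed form)."""

    family = "ols"

    def __init__(self, endog, exog):
        self.exog = _as_design(exog)
        self.endog = pd.Series(np.asarray(endog, dtype=float),
                               index=self.exog.index, name="utility")
        if len(self.endog) <= self.exog.shape[1]:
            raise DataError(
                f"n={len(self.endog)} must exceed the number of predictors "
                f"({self.exog.shape[1]})"
            )
        _check_rank(self.exog)

    def fit(self) -> MappingResults:
        res = sm.OLS(self.endog.to_numpy(), self.exog.to_numpy()).fit()
        params = pd.Series(res.params, index=self.exog.columns)
        cov = pd.DataFrame(res.cov_params(), index=self.exog.columns,
                           columns=self.exog.columns)
        out = MappingResults(
            self, params, cov, llf=res.llf, nobs=int(res.nobs),
            k_params=self.exog.shape[1],
            scale=float(np.sqrt(res.scale)),
            extra={"r2_adj": float(res.rsquared_adj),
                   "r2": float(res.rsquared)},
            use_t=True, df_resid=res.df_resid,
        )
        out._sm = res  # keep the statsmodels object reachable for diagnostics
        return out

    def _predict(self, params, X, mode=None):
        beta = params[X.columns]
        return pd.Series(X.to_numpy() @ beta.to_numpy(), index=X.index)


# ---------------------------------------------------------------------------
# Tobit (upper-censored Gaussian MLE)
# ---------------------------------------------------------------------------


class TobitMapper:
    """Gaussian regression with the outcome censored above at ``upper``.

    Observed y = min(y*, upper) with y* = X beta + sigma * eps.  Censored
    observations contribute P(y* >= upper) to the likelihood.  The default
    prediction is the censored expectation E[min(y*, upper) | x], which can
    never exceed the limit; ``mode="latent"`` returns X beta.
    """

    family = "tobit"

    def __init__(self, endog, exog, upper: float = 1.0):
        self.exog = _as_design(exog)
        self.endog = pd.Series(np.asarray(endog, dtype=float),
                               index=self.exog.index, name="utility")
        self.upper = float(upper)
        if (self.endog > self.upper + 1e-12).any():
            raise DataError(f"outcomes above the censoring limit {self.upper}")
        self._cens = np.isclose(self.endog.to_numpy(), self.upper,
                                rtol=0.0, atol=1e-12)
        if self._cens.all():
            raise DataError("all observations censored: model not identifiable")
        _check_rank(self.exog)

    # parameter vector: (beta..., log sigma)
    def loglike_obs(self, theta: np.ndarray) -> np.ndarray:
        X = self.exog.to_numpy()
        y = self.endog.to_numpy()
        beta, logs = theta[:-1], theta[-1]
        sigma = np.exp(logs)
        xb = X @ beta
        ll = np.empty(len(y))
        unc = ~self._cens
        e = (y[unc] - xb[unc]) / sigma
        ll[unc] = -0.5 * e**2 - np.log(sigma * _SQRT2PI)
        a = (xb[self._cens] - self.upper) / sigma
        ll[self._cens] = log_ndtr(a)
        return ll

    def loglike(self, theta):
        return float(self.loglike_obs(theta).sum())

    def score_obs(self, theta: np.ndarray) -> np.ndarray:
        X = self.exog.to_numpy()
        y = self.endog.to_numpy()
        beta, logs = theta[:-1], theta[-1]
        sigma = np.exp(logs)
        xb = X @ beta
        g = np.zeros((len(y), len(theta)))
        unc = ~self._cens
        e = (y[unc] - xb[unc]) / sigma
        g[unc, :-1] = X[unc] * (e / sigma)[:, None]
        g[unc, -1] = e**2 - 1.0
        a = (xb[self._cens] - self.upper) / sigma
        mills = np.exp(stats.norm.logpdf(a) - log_ndtr(a))
        g[self._cens, :-1] = X[self._cens] * (mills / sigma)[:, None]
        g[self._cens, -1] = -a * mills
        return g

    def score(self, theta):
        return self.score_obs(theta).sum(axis=0)

    def _start(self) -> np.ndarray:
        ols = sm.OLS(self.endog.to_numpy(), self.exog.to_numpy()).fit()
        sigma0 = max(np.sqrt(ols.scale), 1e-4)
        return np.concatenate([ols.params, [np.log(sigma0)]])

    def _fit_params(self, start_params=None, maxiter: int = 500,
                    gtol: float = 1e-8) -> np.ndarray:
        theta0 = self._start() if start_params is None else np.asarray(start_params)
        res = scipy.optimize.minimize(
            lambda t: -self.loglike(t), theta0,
            jac=lambda t: -self.score(t),
            method="BFGS",
            options={"maxiter": maxiter, "gtol": gtol},
        )
        x, nit = res.x, res.nit
        gnorm = float(np.max(np.abs(self.score(x))))
        if gnorm > self._gtol_accept(gtol):
            # one polish pass; BFGS sometimes halts on precision loss short
            # of a usable stationary point
            res2 = scipy.optimize.minimize(
                lambda t: -self.loglike(t), x,
                jac=lambda t: -self.score(t),
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol},
            )
            if -res2.fun >= self.loglike(x):
                x, nit = res2.x, nit + res2.nit
            gnorm = float(np.max(np.abs(self.score(x))))
        if gnorm > self._gtol_accept(gtol):
            raise ConvergenceError(
                f"{type(self).__name__} did not converge: |grad|={gnorm:.3g}, "
                f"iterations={nit}, message={res.message!r}"
            )
        return x

    def _gtol_accept(self, gtol: float) -> float:
        # stationarity tolerance scales with the log-likelihood magnitude
        return max(gtol, 1e-6 * len(self.endog))

    def _column_scales(self) -> np.ndarray:
        scales = np.sqrt((self.exog.to_numpy() ** 2).mean(axis=0))
        scales[~np.isfinite(scales) | (scales == 0)] = 1.0
        return scales

    def fit(self, start_params=None, maxiter: int = 500,
            gtol: float = 1e-8) -> MappingResults:
        # fit on unit-RMS columns for optimizer conditioning, map back after
        scales = self._column_scales()
        sub = type(self)(self.endog, self.exog / scales, **self._family_kwargs())
        if start_params is not None:
            start_params = np.concatenate(
                [np.asarray(start_params)[:-1] * scales,
                 [np.asarray(start_params)[-1]]]
            )
        theta_s = sub._fit_params(start_params, maxiter, gtol)
        cov_s = sub._cov(theta_s)
        d = np.concatenate([1.0 / scales, [1.0]])
        theta = theta_s * d
        cov = cov_s * np.outer(d, d)
        return self._results(theta, cov)

    def _cov(self, theta: np.ndarray) -> np.ndarray:
        H = numdiff.approx_fprime(theta, self.score, centered=True)
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = None
        if cov is None or not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            g = self.score_obs(theta)
            cov = np.linalg.pinv(g.T @ g)
        return cov

    def _results(self, theta: np.ndarray, cov: np.ndarray | None = None) -> MappingResults:
        names = list(self.exog.columns) + ["log_sigma"]
        if cov is None:
            cov = self._cov(theta)
        cov = pd.DataFrame(cov, index=names, columns=names)
        params = pd.Series(theta, index=names)
        llf = self.loglike(theta)
        extra = {"converged": True, "sigma": float(np.exp(theta[-1])),
                 "n_censored": int(self._cens.sum()) if hasattr(self, "_cens") else 0}
        extra["pseudo_r2"] = self._pseudo_r2(llf)
        return MappingResults(
            self, params, cov, llf=llf, nobs=len(self.endog),
            k_params=len(theta), scale=float(np.exp(theta[-1])), extra=extra,
        )

    def _pseudo_r2(self, llf: float) -> float:
        """McFadden pseudo R-squared against the intercept-only model."""
        null = type(self)(self.endog,
                          pd.DataFrame({"const": np.ones(len(self.endog))},
                                       index=self.endog.index),
                          **self._family_kwargs())
        try:
            llnull = null.loglike(null._fit_params())
        except ConvergenceError:
            return float("nan")
        return float(1.0 - llf / llnull) if llnull != 0 else float("nan")

    def _family_kwargs(self) -> dict:
        return {"upper": self.upper}

    def _predict(self, params, X, mode=None):
        beta = params[X.columns]
        xb = X.to_numpy() @ beta.to_numpy()
        if mode == "latent":
            return pd.Series(xb, index=X.index)
        sigma = float(np.exp(params["log_sigma"]))
        a = (self.upper - xb) / sigma
        # E[min(y*, U)] = U*(1-Phi(a)) + Phi(a)*xb - sigma*phi(a)
        ey = self.upper * (1 - ndtr(a)) + ndtr(a) * xb - sigma * stats.norm.pdf(a)
        return pd.Series(ey, index=X.index)


# ---------------------------------------------------------------------------
# Truncated Gaussian regression (two-part model, part 2)
# ---------------------------------------------------------------------------


class TruncatedMapper(TobitMapper):
    """Gaussian regression truncated to the interval ``bounds``.

    Used for the sub-ceiling part of the two-part model, where utilities of
    respondents below full health lie in (-0.594, 0.99).  The default
    prediction is the linear predictor X beta (matching how such mappings
    are commonly applied); ``mode="conditional"`` returns the
    truncated-normal conditional mean E[y | L < y < U, x].
    """

    family = "truncated"

    def __init__(self, endog, exog, bounds: tuple[float, float] = DEFAULT_TRUNC_BOUNDS):
        self.exog = _as_design(exog)
        self.endog = pd.Series(np.asarray(endog, dtype=float),
                               index=self.exog.index, name="utility")
        self.lower, self.upper = (float(bounds[0]), float(bounds[1]))
        if self.lower >= self.upper:
            raise ValueError("lower bound must be below upper bound")
        y = self.endog.to_numpy()
        if (y < self.lower - 1e-12).any() or (y > self.upper + 1e-12).any():
            raise DataError(
                f"outcomes outside the truncation interval "
                f"[{self.lower}, {self.upper}]"
            )
        _check_rank(self.exog)

    def _trunc_terms(self, xb, sigma):
        bu = (self.upper - xb) / sigma
        bl = (self.lower - xb) / sigma
        D = ndtr(bu) - ndtr(bl)
        return bu, bl, np.clip(D, 1e-300, None)

    def loglike_obs(self, theta: np.ndarray) -> np.ndarray:
        X = self.exog.to_numpy()
        y = self.endog.to_numpy()
        beta, logs = theta[:-1], theta[-1]
        sigma = np.exp(logs)
        xb = X @ beta
        e = (y - xb) / sigma
        _, _, D = self._trunc_terms(xb, sigma)
        return -0.5 * e**2 - np.log(sigma * _SQRT2PI) - np.log(D)

    def score_obs(self, theta: np.ndarray) -> np.ndarray:
        X = self.exog.to_numpy()
        y = self.endog.to_numpy()
        beta, logs = theta[:-1], theta[-1]
        sigma = np.exp(logs)
        xb = X @ beta
        e = (y - xb) / sigma
        bu, bl, D = self._trunc_terms(xb, sigma)
        pu, pl = stats.norm.pdf(bu), stats.norm.pdf(bl)
        gb = (e + (pu - pl) / D) / sigma
        gs = e**2 - 1.0 + (pu * bu - pl * bl) / D
        return np.column_stack([X * gb[:, None], gs])

    def _family_kwargs(self) -> dict:
        return {"bounds": (self.lower, self.upper)}

    def _predict(self, params, X, mode=None):
        beta = params[X.columns]
        xb = X.to_numpy() @ beta.to_numpy()
        if mode in (None, "linear"):
            return pd.Series(xb, index=X.index)
        if mode != "conditional":
            raise ValueError(f"unknown prediction mode {mode!r}")
        sigma = float(np.exp(params["log_sigma"]))
        bu, bl, D = self._trunc_terms(xb, sigma)
        cond = xb + sigma * (stats.norm.pdf(bl) - stats.norm.pdf(bu)) / D
        return pd.Series(cond, index=X.index)


# ---------------------------------------------------------------------------
# Logit (two-part model, part 1)
# ---------------------------------------------------------------------------


class LogitMapper:
    """Logit for the probability of being at the utility ceiling."""

    family = "logit"

    def __init__(self, endog, exog):
        self.exog = _as_design(exog)
        z = np.asarray(endog, dtype=float)
        if not set(np.unique(z)) <= {0.0, 1.0}:
            raise DataError("logit outcome must be binary 0/1")
        if z.min() == z.max():
            raise DataError("both outcome classes must be present")
        self.endog = pd.Series(z, index=self.exog.index, name="ceiling")
        _check_rank(self.exog)

    def fit(self, maxiter: int = 200) -> MappingResults:
        import warnings

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(self.endog.to_numpy(), self.exog.to_numpy()).fit(
                    disp=0, maxiter=maxiter, method="newton"
                )
        except Exception as exc:  # statsmodels PerfectSeparationError etc.
            raise SeparationError(
                f"logit fit failed ({exc}); check for separating predictors"
            ) from exc
        params = pd.Series(res.params, index=self.exog.columns)
        bse = np.sqrt(np.diag(res.cov_params()))
        if (np.any(~np.isfinite(bse)) or np.max(np.abs(res.params)) > 50
                or not res.mle_retvals["converged"]):
            worst = self.exog.columns[int(np.argmax(np.abs(res.params)))]
            raise SeparationError(
                "perfect or quasi-separation (or non-convergence) detected; "
                f"most extreme predictor: {worst!r}"
            )
        cov = pd.DataFrame(res.cov_params(), index=self.exog.columns,
                           columns=self.exog.columns)
        out = MappingResults(
            self, params, cov, llf=res.llf, nobs=int(res.nobs),
            k_params=self.exog.shape[1],
            extra={"pseudo_r2": float(res.prsquared),
                   "converged": bool(res.mle_retvals["converged"])},
        )
        out._sm = res
        return out

    def _predict(self, params, X, mode=None):
        beta = params[X.columns]
        xb = X.to_numpy() @ beta.to_numpy()
        if mode == "linear":
            return pd.Series(xb, index=X.index)
        return pd.Series(1.0 / (1.0 + np.exp(-xb)), index=X.index)


# ---------------------------------------------------------------------------
# Two-part model
# ---------------------------------------------------------------------------


def tpm_predict(p, yhat2):
    """Expected-value combination of the two parts.

    ``EV = p * 1 + (1 - p) * yhat2`` with p = Pr(utility = 1); vectorized.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("ceiling probabilities must lie in [0, 1]")
    yhat2 = np.asarray(yhat2, dtype=float)
    out = p * 1.0 + (1.0 - p) * yhat2
    return float(out) if out.ndim == 0 else out


@dataclass
class TwoPartResults:
    """Results bundle for the two-part model (criteria kept per part)."""

    model: "TwoPartMapper"
    part1: MappingResults
    part2: MappingResults
    family: str = "tpm"

    def predict(self, exog1=None, exog2=None, part2_mode: str | None = None):
        p = self.part1.predict(exog1)
        yhat2 = self.part2.predict(
            self.model.exog2 if exog2 is None else _as_design(exog2),
            mode=part2_mode,
        )
        ev = tpm_predict(p.to_numpy(), yhat2.to_numpy())
        return pd.Series(ev, index=p.index, name="ev_utility")

    @property
    def aic(self) -> tuple[float, float]:
        return (self.part1.aic, self.part2.aic)

    @property
    def bic(self) -> tuple[float, float]:
        return (self.part1.bic, self.part2.bic)

    @property
    def nobs(self) -> int:
        return self.part1.nobs

    def summary(self) -> str:
        return (
            "Two-part model\n=== Part 1 (logit, Pr[utility = 1]) ===\n"
            + self.part1.summary()
            + "\n=== Part 2 (truncated regression, utility < 1) ===\n"
            + self.part2.summary()
        )


class TwoPartMapper:
    """Two-part model: ceiling logit + truncated regression below ceiling.

    ``exog1`` (part-1 design, full sample) and ``exog2`` (part-2 design,
    full sample; rows at the ceiling are used only for prediction) may
    differ — the specification ladder screens each part separately.
    """

    family = "tpm"

    def __init__(self, endog, exog1, exog2=None, ceiling: float = 1.0,
                 bounds: tuple[float, float] = DEFAULT_TRUNC_BOUNDS):
        self.exog1 = _as_design(exog1)
        self.exog2 = self.exog1 if exog2 is None else _as_design(exog2)
        y = pd.Series(np.asarray(endog, dtype=float), index=self.exog1.index)
        self.endog = y
        self.ceiling = float(ceiling)
        self.bounds = bounds
        self._at_ceiling = np.isclose(y.to_numpy(), ceiling, rtol=0, atol=1e-12)
        if self._at_ceiling.all() or not self._at_ceiling.any():
            raise DataError("two-part model needs both ceiling and "
                            "sub-ceiling respondents")

    def fit(self) -> TwoPartResults:
        part1 = LogitMapper(self._at_ceiling.astype(float), self.exog1).fit()
        sub = ~self._at_ceiling
        part2 = TruncatedMapper(
            self.endog[sub], self.exog2.loc[sub], bounds=self.bounds
        ).fit()
        return TwoPartResults(self, part1, part2)


# ---------------------------------------------------------------------------
# Functional wrappers (one per estimator operation)
# ---------------------------------------------------------------------------


def fit_ols(X, y) -> MappingResults:
    return OLSMapper(y, X).fit()


def fit_tobit(X, y, upper: float = 1.0) -> MappingResults:
    return TobitMapper(y, X, upper=upper).fit()


def fit_logit(X, z) -> MappingResults:
    return LogitMapper(z, X).fit()


def fit_truncated(X, y, bounds: tuple[float, float] = DEFAULT_TRUNC_BOUNDS) -> MappingResults:
    return TruncatedMapper(y, X, bounds=bounds).fit()


def fit_two_part(X1, y, X2=None, bounds: tuple[float, float] = DEFAULT_TRUNC_BOUNDS) -> TwoPartResults:
    return TwoPartMapper(y, X1, exog2=X2, bounds=bounds).fit()


# ---------------------------------------------------------------------------
# Bias-corrected bootstrap
# ---------------------------------------------------------------------------


def bootstrap_bc(
    fit_fn,
    data: pd.DataFrame,
    reps: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
    max_fail_share: float = 0.10,
) -> pd.DataFrame:
    """Bias-corrected (BC) bootstrap SEs and intervals for a fit procedure.

    ``fit_fn(df) -> pd.Series`` of named estimates.  Respondents (rows) are
    resampled with replacement; SE is the SD of the bootstrap estimates; the
    BC interval applies the median-bias correction
    z0 = ndtri(share of bootstrap estimates below the point estimate) to the
    percentile interval.  Degenerate cases (all bootstrap estimates equal)
    collapse to a zero-width interval at the point estimate.

    Returns a DataFrame indexed by coefficient with columns
    ``estimate, se, ci_lower, ci_upper, z0``; the seed and replication count
    are recorded in ``DataFrame.attrs``.
    """
    if reps < 2:
        raise ValueError("reps must be at least 2")
    point = fit_fn(data)
    rng = np.random.default_rng(seed)
    n = len(data)
    draws, failures = [], 0
    for _ in range(reps):
        idx = rng.integers(0, n, n)
        try:
            draws.append(fit_fn(data.iloc[idx]))
        except Exception:
            failures += 1
    if failures > max_fail_share * reps:
        raise RuntimeError(
            f"bootstrap fit failed in {failures}/{reps} resamples "
            f"({failures / reps:.1%} > {max_fail_share:.0%} allowed)"
        )
    boot = pd.DataFrame(draws)[point.index]
    se = boot.std(ddof=1)
    z_alpha = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    rows = {}
    for name in point.index:
        b = boot[name].to_numpy()
        est = point[name]
        if np.allclose(b, b[0]):
            rows[name] = (est, 0.0, est, est, 0.0)
            continue
        share_below = np.mean(b < est)
        z0 = ndtri(np.clip(share_below, 1.0 / len(b), 1 - 1.0 / len(b)))
        qs = ndtr(2 * z0 + z_alpha)  # BC-adjusted percentile levels
        lo, hi = np.quantile(b, qs)
        rows[name] = (est, se[name], lo, hi, z0)
    out = pd.DataFrame(
        rows, index=["estimate", "se", "ci_lower", "ci_upper", "z0"]
    ).T
    out.attrs.update({"reps": reps, "seed": seed, "alpha": alpha,
                      "failures": failures, "method": "bias-corrected (BC)"})
    return out
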