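"""OLS, spatial lag, and spatial error regression with ML estimation.

The three model classes share the statsmodels idiom: construct from data,
call :meth:`fit`, receive a :class:`RegressionResults` carrying estimates,
standard errors, p-values, the log-likelihood, and the AIC.

The spatial models are simultaneous-autoregressive specifications over a
row-standardized weights matrix W:

* spatial lag:    y = rho * W y + X beta + eps
* spatial error:  y = X beta + u,   u = lambda * W u + eps

Both are estimated by maximizing the profile log-likelihood of the
autocorrelation coefficient, with beta and sigma^2 concentrated out in
closed form at each candidate value and the Jacobian term log|I - c W|
evaluated through the (cached) spectrum of W.  AIC uses a parameter count
of (#coefficients incl. intercept) + 1 for the error variance + 1 for the
spatial coefficient where present, so the three model classes are
comparable on the same scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .weights import SpatialWeights

__all__ = [
    "RegressionResults",
    "OLS",
    "SpatialLag",
    "SpatialError",
    "fit_ols",
    "fit_spatial_lag",
    "fit_spatial_error",
    "aic_from_loglike",
    "aic",
    "vif",
    "morans_i",
    "MoranResult",
    "prune_covariates",
]

LOG2PI = float(np.log(2.0 * np.pi))


def aic_from_loglike(llf: float, k_params: int) -> float:
    """Akaike Information Criterion, -2 logL + 2 k."""
    return -2.0 * llf + 2.0 * k_params


def _design(X, add_constant: bool) -> pd.DataFrame:
    """Design matrix as a DataFrame, optionally with a leading constant."""
    if isinstance(X, pd.DataFrame):
        df = X.copy()
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    if add_constant and "const" not in df.columns:
        df.insert(0, "const", 1.0)
    return df.astype(float)


def _check_rank(df: pd.DataFrame) -> None:
    """Raise on rank deficiency, naming the dependent columns."""
    A = df.to_numpy()
    q, r, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < df.shape[1]:
        bad = [df.columns[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear column(s): {bad}"
        )


@dataclass
class RegressionResults:
    """Estimates and diagnostics for one fitted regression.

    ``params``/``bse``/``pvalues`` are indexed by exogenous-variable name.
    ``spatial_coef`` holds rho (lag) or lambda (error) and is None for OLS.
    ``resid`` holds the innovation residuals (for the spatial models, the
    residuals after spatial filtering).  ``aic`` counts the coefficients,
    the error variance, and the spatial coefficient where present.
    """

    model: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    nobs: int
    k_params: int
    resid: np.ndarray
    sigma2: float
    rsquared: Optional[float] = None
    spatial_coef: Optional[float] = None
    spatial_coef_se: Optional[float] = None
    spatial_coef_pvalue: Optional[float] = None
    aic: float = field(init=False)

    def __post_init__(self) -> None:
        self.aic = aic_from_loglike(self.llf, self.k_params)

    @property
    def exog_names(self) -> list:
        return list(self.params.index)

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        out = {
            "model": self.model,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "llf": self.llf,
            "aic": self.aic,
            "nobs": int(self.nobs),
            "k_params": int(self.k_params),
            "sigma2": self.sigma2,
        }
        if self.rsquared is not None:
            out["rsquared"] = self.rsquared
        if self.spatial_coef is not None:
            out["spatial_coef"] = self.spatial_coef
            out["spatial_coef_se"] = self.spatial_coef_se
            out["spatial_coef_pvalue"] = self.spatial_coef_pvalue
        return out

    def summary(self) -> str:
        name = {"ols": "OLS", "lag": "Spatial lag (ML)", "error": "Spatial error (ML)"}[
            self.model
        ]
        lines = [
            f"{name} regression results",
            "=" * 64,
            f"n obs: {self.nobs:>8d}    parameters: {self.k_params}",
            f"log-likelihood: {self.llf:14.4f}    AIC: {self.aic:12.4f}",
        ]
        if self.rsquared is not None:
            lines.append(f"R-squared: {self.rsquared:.4f}")
        lines.append("-" * 64)
        lines.append(f"{'variable':<20s}{'coef':>12s}{'std err':>12s}{'P>|z|':>12s}")
        for name_ in self.params.index:
            lines.append(
                f"{str(name_):<20s}{self.params[name_]:>12.4f}"
                f"{self.bse[name_]:>12.4f}{self.pvalues[name_]:>12.4g}"
            )
        if self.spatial_coef is not None:
            label = "rho (lag)" if self.model == "lag" else "lambda (error)"
            se = self.spatial_coef_se if self.spatial_coef_se is not None else float("nan")
            pv = (
                self.spatial_coef_pvalue
                if self.spatial_coef_pvalue is not None
                else float("nan")
            )
            lines.append(f"{label:<20s}{self.spatial_coef:>12.4f}{se:>12.4f}{pv:>12.4g}")
        lines.append("=" * 64)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

class OLS:
    """Ordinary least squares with the Gaussian ML log-likelihood.

    The variance estimate entering the likelihood is sigma^2 = RSS/n (ML,
    not REML), which keeps AIC comparable with the spatial models.
    """

    def __init__(self, endog, exog, add_constant: bool = True):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = _design(exog, add_constant)
        if len(self.endog) != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        _check_rank(self.exog)
        if len(self.endog) <= self.exog.shape[1] + 1:
            raise ValueError("need n_obs > n_params")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, covariates: Sequence[str]):
        return cls(df[outcome], df[list(covariates)])

    def loglike_at_rss(self, rss: float) -> float:
        n = len(self.endog)
        return -0.5 * n * (LOG2PI + 1.0 + np.log(rss / n))

    def fit(self) -> RegressionResults:
        res = sm.OLS(self.endog, self.exog).fit()
        n = len(self.endog)
        p = self.exog.shape[1]
        rss = float(res.ssr)
        return RegressionResults(
            model="ols",
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            llf=float(res.llf),
            nobs=n,
            k_params=p + 1,
            resid=np.asarray(res.resid, dtype=float),
            sigma2=rss / n,
            rsquared=float(res.rsquared),
        )


def fit_ols(X, y, add_constant: bool = True) -> RegressionResults:
    """Fit ``y ~ X`` by OLS; convenience wrapper over :class:`OLS`."""
    return OLS(y, X, add_constant=add_constant).fit()


# ---------------------------------------------------------------------------
# spatial ML models
# ---------------------------------------------------------------------------

class _SpatialML:
    """Shared machinery for the lag and error models."""

    model_name = ""

    def __init__(
        self,
        endog,
        exog,
        weights: SpatialWeights,
        add_constant: bool = True,
        allow_isolated: bool = False,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = _design(exog, add_constant)
        _check_rank(self.exog)
        n = len(self.endog)
        if weights.n != n or len(self.exog) != n:
            raise ValueError("weights, endog and exog sizes must agree")
        if weights.isolated_ids() and not allow_isolated:
            raise ValueError(
                "weights matrix has isolated regions; pass allow_isolated=True to override"
            )
        if not weights.row_standardized:
            weights = weights.row_standardize()
        self.weights = weights
        self.W = weights.matrix
        self.n = n
        self.X = self.exog.to_numpy()
        self.p = self.X.shape[1]
        self._prepare()

    # -- subclass hooks -------------------------------------------------
    def _prepare(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def _concentrated(self, coef: float) -> Tuple[np.ndarray, np.ndarray]:
        """(beta_hat, innovation residuals) at a fixed spatial coefficient."""
        raise NotImplementedError

    def loglike(self, coef: float) -> float:
        """Profile log-likelihood at a fixed spatial coefficient.

        At coef = 0 this equals the OLS log-likelihood exactly (the models
        nest ordinary regression).
        """
        _, e = self._concentrated(coef)
        sig2 = float(e @ e) / self.n
        return (
            -0.5 * self.n * (LOG2PI + 1.0 + np.log(sig2)) + self.weights.log_det(coef)
        )

    def _full_loglike(self, beta: np.ndarray, coef: float, sig2: float) -> float:
        e = self._innovations(beta, coef)
        return (
            -0.5 * self.n * (LOG2PI + np.log(sig2))
            + self.weights.log_det(coef)
            - float(e @ e) / (2.0 * sig2)
        )

    def _innovations(self, beta: np.ndarray, coef: float) -> np.ndarray:
        raise NotImplementedError

    # -- estimation -----------------------------------------------------
    def fit(self, tol: float = 1e-6, coarse: int = 64) -> RegressionResults:
        """Maximize the profile likelihood over the admissible interval.

        A coarse scan brackets the optimum, then bounded scalar search
        shrinks the interval to ``tol``.  Deterministic: no random starts.
        """
        lo, hi = self.weights.coef_bounds()
        lo, hi = max(lo, -1.0 + 1e-7) + 1e-7, min(hi, 1.0 - 1e-7) - 1e-7
        grid = np.linspace(lo, hi, coarse)
        vals = np.array([self.loglike(c) for c in grid])
        j = int(np.argmax(vals))
        blo = grid[max(j - 1, 0)]
        bhi = grid[min(j + 1, coarse - 1)]
        opt = scipy.optimize.minimize_scalar(
            lambda c: -self.loglike(c),
            bounds=(blo, bhi),
            method="bounded",
            options={"xatol": tol},
        )
        coef = float(opt.x)
        beta, e = self._concentrated(coef)
        sig2 = float(e @ e) / self.n
        llf = self.loglike(coef)
        bse, coef_se, pvals, coef_p = self._wald(beta, coef, sig2)
        params = pd.Series(beta, index=self.exog.columns)
        return RegressionResults(
            model=self.model_name,
            params=params,
            bse=pd.Series(bse, index=self.exog.columns),
            pvalues=pd.Series(pvals, index=self.exog.columns),
            llf=float(llf),
            nobs=self.n,
            k_params=self.p + 2,
            resid=e,
            sigma2=sig2,
            spatial_coef=coef,
            spatial_coef_se=coef_se,
            spatial_coef_pvalue=coef_p,
        )

    def _wald(self, beta: np.ndarray, coef: float, sig2: float):
        """SEs from the inverse numerical Hessian of the full log-likelihood."""
        x0 = np.concatenate([beta, [coef, sig2]])

        def f(v: np.ndarray) -> float:
            return self._full_loglike(v[: self.p], v[self.p], max(v[-1], 1e-12))

        m = len(x0)
        h = 1e-5 * (1.0 + np.abs(x0))
        H = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m); ei[i] = h[i]
                ej = np.zeros(m); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4.0 * h[i] * h[j])
        try:
            cov = np.linalg.inv(-H)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            se = np.sqrt(d)
        except np.linalg.LinAlgError:  # pragma: no cover
            warnings.warn("Hessian not invertible; standard errors unavailable")
            se = np.full(m, np.nan)
        bse = se[: self.p]
        coef_se = float(se[self.p])
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta / bse
            pvals = 2.0 * scipy.stats.norm.sf(np.abs(z))
            coef_p = float(2.0 * scipy.stats.norm.sf(abs(coef / coef_se)))
        return bse, coef_se, pvals, coef_p


class SpatialLag(_SpatialML):
    """ML spatial lag model y = rho W y + X beta + eps."""

    model_name = "lag"

    def _prepare(self) -> None:
        y = self.endog
        Wy = self.W @ y
        self._Wy = Wy
        b_o, *_ = np.linalg.lstsq(self.X, y, rcond=None)
        b_l, *_ = np.linalg.lstsq(self.X, Wy, rcond=None)
        self._b_o, self._b_l = b_o, b_l
        self._e_o = y - self.X @ b_o
        self._e_l = Wy - self.X @ b_l

    def _concentrated(self, rho: float):
        beta = self._b_o - rho * self._b_l
        e = self._e_o - rho * self._e_l
        return beta, e

    def _innovations(self, beta: np.ndarray, rho: float) -> np.ndarray:
        return self.endog - rho * self._Wy - self.X @ beta


class SpatialError(_SpatialML):
    """ML spatial error model y = X beta + u, u = lambda W u + eps.

    Estimated by generalized least squares on the spatially filtered
    variables (I - lambda W) y and (I - lambda W) X at each candidate
    lambda, plus the log-determinant Jacobian.
    """

    model_name = "error"

    def _prepare(self) -> None:
        self._Wy = self.W @ self.endog
        self._WX = self.W @ self.X

    def _concentrated(self, lam: float):
        ys = self.endog - lam * self._Wy
        Xs = self.X - lam * self._WX
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ beta
        return beta, e

    def _innovations(self, beta: np.ndarray, lam: float) -> np.ndarray:
        u = self.endog - self.X @ beta
        return u - lam * (self.W @ u)


def fit_spatial_lag(X, y, weights: SpatialWeights, **kwargs) -> RegressionResults:
    """Fit the spatial lag model; see :class:`SpatialLag`."""
    fit_kw = {k: kwargs.pop(k) for k in ("tol", "coarse") if k in kwargs}
    return SpatialLag(y, X, weights, **kwargs).fit(**fit_kw)


def fit_spatial_error(X, y, weights: SpatialWeights, **kwargs) -> RegressionResults:
    """Fit the spatial error model; see :class:`SpatialError`."""
    fit_kw = {k: kwargs.pop(k) for k in ("tol", "coarse") if k in kwargs}
    return SpatialError(y, X, weights, **kwargs).fit(**fit_kw)


def aic(results: RegressionResults) -> float:
    """AIC of a fitted model (convenience accessor)."""
    return results.aic


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_a = 1 / (1 - R^2_a).

    Each column is regressed (with intercept) on the remaining columns.
    Perfectly collinear columns report ``inf`` rather than raising.
    """
    X = _design(X, add_constant=False)
    if "const" in X.columns:
        X = X.drop(columns="const")
    if X.shape[1] < 2:
        raise ValueError("VIF requires at least 2 non-intercept columns")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col))
        r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass(frozen=True)
class MoranResult:
    I: float
    p_value: float
    expected: float
    n_permutations: int


def morans_i(
    values,
    weights: SpatialWeights,
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> MoranResult:
    """Global Moran's I with a one-sided (greater) permutation p-value.

    I = (n / S0) * (z' W z) / (z' z) with z the mean-centered values and S0
    the sum of all weights.  The null expectation is -1/(n-1).  The p-value
    counts permutations with I at least as large as observed (positive
    autocorrelation alternative), with the observed arrangement included in
    the reference set.
    """
    v = np.asarray(values, dtype=float)
    if weights.n != len(v):
        raise ValueError("values length must match weights")
    z = v - v.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I is undefined for a constant vector")
    W = weights.matrix
    s0 = float(W.sum())
    n = len(v)
    obs = (n / s0) * float(z @ (W @ z)) / denom
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        zp = rng.permutation(z)
        ip = (n / s0) * float(zp @ (W @ zp)) / denom
        if ip >= obs:
            count += 1
    p = (count + 1.0) / (n_permutations + 1.0)
    return MoranResult(I=obs, p_value=p, expected=-1.0 / (n - 1), n_permutations=n_permutations)


def prune_covariates(
    X: pd.DataFrame,
    y,
    fit_fn: Callable[..., RegressionResults] = fit_ols,
    alpha: float = 0.05,
    protected: Sequence[str] = (),
    **fit_kwargs,
) -> Tuple[RegressionResults, list]:
    """Backward elimination: drop the least significant covariate until all
    remaining terms are significant at ``alpha``.

    The intercept and any column named in ``protected`` (typically the
    exposure term) are never removed.  Ties in the largest p-value are broken
    by column order, so the procedure is deterministic for a given input.
    Returns the final fit and the list of kept columns.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    X = _design(X, add_constant=False)
    if "const" in X.columns:
        X = X.drop(columns="const")
    protected = set(protected)
    cols = list(X.columns)
    while True:
        if not cols:
            raise ValueError("all covariates removed; cannot refit")
        fit = fit_fn(X[cols], y, **fit_kwargs)
        pv = fit.pvalues.drop(index="const", errors="ignore")
        candidates = pv[[c for c in cols if c not in protected]]
        if candidates.empty or (candidates < alpha).all():
            return fit, cols
        worst = candidates.idxmax()
        if candidates[worst] < alpha:
            return fit, cols
        cols = [c for c in cols if c != worst]
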