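"""Set-level comparisons across CpG sites.

Two meta-analytic tools operate on per-site, per-occasion estimates from the
twin fits:

* a random-intercept linear mixed model (site = grouping factor, two occasion
  rows per site) comparing categories of sites — island relation, clock or
  aging-set membership — with a Wald chi-square on the category coefficients
  and the intraclass ratio rho = sigma_between^2 / (sigma_between^2 +
  sigma_within^2) measuring how site-specific (vs. occasion-specific) the
  estimates are;
* a skew-normal regression of Fisher-Z cross-time correlations on a group
  indicator, whose fitted group means are inverse-transformed (tanh) back to
  correlation units.  Fisher-Z distributions of path-derived correlations
  pile up near the |r| = 1 boundary, hence the skewed error law.

The LMM is estimated by maximum likelihood (not REML) so Wald tests on fixed
effects are coherent across fits; estimation is delegated to statsmodels
MixedLM.  The skew-normal regression is fitted by direct maximum likelihood
over the scipy skew-normal density with multiple shape starts (the direct
parametrization has a flat direction at shape = 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "LMMResult",
    "SkewFit",
    "RandomInterceptModel",
    "SkewNormalRegression",
    "fit_random_intercept_lmm",
    "compare_sets",
    "skew_regress_z",
]

_SQRT_2_PI = math.sqrt(2.0 / math.pi)


@dataclass
class LMMResult:
    """Random-intercept LMM fit: fixed effects, variance components, Wald test."""

    fixed_effects: pd.Series
    fixed_se: pd.Series
    var_between: float
    var_within: float
    wald_chi2: Optional[float]
    wald_df: Optional[int]
    p: Optional[float]
    converged: bool

    @property
    def rho(self) -> float:
        total = self.var_between + self.var_within
        return self.var_between / total if total > 0 else np.nan


@dataclass
class SkewFit:
    """Skew-normal regression fit on the Fisher-Z scale."""

    coef: pd.Series  # location coefficients
    scale: float
    shape: float
    loglik: float
    group_mean_z: dict  # group label -> fitted mean on the Z scale
    group_r: dict  # group label -> tanh(fitted mean)
    group_diff_p: Optional[float]  # Wald p for the group coefficient
    converged: bool
    normal_fallback: bool = False


class RandomInterceptModel:
    """Random-intercept LMM over per-site x occasion estimates.

    Thin estimator around statsmodels MixedLM fitted by ML.  ``fit`` expects a
    long table with one row per site-occasion, the response column, a site-id
    column and optionally a categorical column whose levels are jointly Wald-
    tested (df = levels - 1, reference level absorbed in the intercept).
    """

    def __init__(self, include_occasion: bool = True):
        self.include_occasion = include_occasion

    def get_params(self, deep: bool = True) -> dict:
        return {"include_occasion": self.include_occasion}

    def set_params(self, **params) -> "RandomInterceptModel":
        for k, v in params.items():
            if k != "include_occasion":
                raise ValueError(f"unknown parameter {k!r}")
            self.include_occasion = v
        return self

    def fit(
        self,
        df: pd.DataFrame,
        response: str,
        category: Optional[str] = None,
        site_col: str = "site_id",
        occasion_col: str = "occasion",
    ) -> "RandomInterceptModel":
        data = df.dropna(subset=[response]).copy()
        if data[site_col].nunique() < 2:
            raise ValueError("need estimates from at least 2 sites")
        exog = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
        if self.include_occasion and occasion_col in data.columns:
            exog["occasion2"] = (data[occasion_col].astype(int) == 2).astype(float)
        category_cols: list[str] = []
        if category is not None:
            levels = sorted(data[category].astype(str).unique())
            if len(levels) >= 2:
                for lev in levels[1:]:
                    col = f"{category}[{lev}]"
                    exog[col] = (data[category].astype(str) == lev).astype(float)
                    category_cols.append(col)
        endog = data[response].to_numpy(dtype=float)
        Xmat = exog.to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # boundary sigma_u^2 = 0 warnings
                model = MixedLM(endog=endog, exog=exog, groups=data[site_col].to_numpy())
                res = model.fit(reml=False, method="lbfgs")
            self.result_ = res
            self.fixed_effects_ = pd.Series(res.fe_params, index=exog.columns)
            self.fixed_se_ = pd.Series(np.asarray(res.bse_fe), index=exog.columns)
            self.var_between_ = float(np.asarray(res.cov_re)[0, 0])
            self.var_within_ = float(res.scale)
            self.converged_ = bool(res.converged)
            self.loglik_ = float(res.llf)
            fe_cov = np.asarray(res.cov_params())[: Xmat.shape[1], : Xmat.shape[1]]
        except np.linalg.LinAlgError:
            # sigma_u^2 on the zero boundary can leave the mixed-model Hessian
            # singular; the ML solution there is exactly the OLS fit
            beta, *_ = np.linalg.lstsq(Xmat, endog, rcond=None)
            resid = endog - Xmat @ beta
            sigma2 = float(np.mean(resid**2))
            fe_cov = sigma2 * np.linalg.inv(Xmat.T @ Xmat)
            self.result_ = None
            self.fixed_effects_ = pd.Series(beta, index=exog.columns)
            self.fixed_se_ = pd.Series(np.sqrt(np.diag(fe_cov)), index=exog.columns)
            self.var_between_ = 0.0
            self.var_within_ = sigma2
            self.converged_ = True
            self.loglik_ = float(
                np.sum(stats.norm.logpdf(endog, Xmat @ beta, np.sqrt(sigma2)))
            )
        if category_cols:
            idx = [exog.columns.get_loc(c) for c in category_cols]
            b = self.fixed_effects_.iloc[idx].to_numpy()
            cov = fe_cov[np.ix_(idx, idx)]
            chi2 = float(b @ np.linalg.solve(cov, b))
            self.wald_chi2_ = chi2
            self.wald_df_ = len(idx)
            self.p_ = float(stats.chi2.sf(chi2, len(idx)))
        else:
            self.wald_chi2_ = self.wald_df_ = self.p_ = None
        self.lmm_result_ = LMMResult(
            fixed_effects=self.fixed_effects_,
            fixed_se=self.fixed_se_,
            var_between=self.var_between_,
            var_within=self.var_within_,
            wald_chi2=self.wald_chi2_,
            wald_df=self.wald_df_,
            p=self.p_,
            converged=self.converged_,
        )
        return self


def fit_random_intercept_lmm(
    df: pd.DataFrame,
    response: str,
    category: Optional[str] = None,
    site_col: str = "site_id",
    occasion_col: str = "occasion",
    include_occasion: bool = True,
) -> LMMResult:
    """Functional wrapper over :class:`RandomInterceptModel`."""
    model = RandomInterceptModel(include_occasion=include_occasion)
    model.fit(df, response, category=category, site_col=site_col, occasion_col=occasion_col)
    return model.lmm_result_


def _component_long(results: pd.DataFrame, component: str) -> pd.DataFrame:
    """Stack <component>_1/<component>_2 columns into site x occasion rows."""
    frames = []
    for t in (1, 2):
        col = f"{component}_{t}"
        if col not in results.columns:
            raise ValueError(f"results table lacks column {col!r}")
        frames.append(
            pd.DataFrame(
                {
                    "site_id": results["site_id"].to_numpy(),
                    "occasion": t,
                    "value": results[col].to_numpy(dtype=float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def compare_sets(
    results: pd.DataFrame,
    set_ids: set,
    components: Sequence[str] = ("broad_h2",),
    best_only: bool = True,
    variant: Optional[str] = None,
) -> pd.DataFrame:
    """Compare a CpG set against the remaining background sites.

    For each requested component (column stem with ``_1``/``_2`` occasion
    suffixes, e.g. ``broad_h2``, ``std_A``, ``abs_E``) a random-intercept LMM
    with set membership as the fixed category is fitted to both occasions'
    estimates; the membership coefficient is the set-vs-background difference.
    """
    df = results[results["best"]] if best_only else results
    if variant is not None:
        df = df[df["variant"] == variant]
    in_set = df["site_id"].isin(set_ids)
    if not in_set.any():
        raise ValueError("the site set does not intersect the results table")
    if in_set.all():
        raise ValueError("the site set covers every site; no background to compare")
    rows = []
    for component in components:
        long = _component_long(df, component)
        long["member"] = long["site_id"].isin(set_ids).astype(int).astype(str)
        res = fit_random_intercept_lmm(long, "value", category="member")
        coef_col = "member[1]"
        rows.append(
            {
                "component": component,
                "n_set": int(in_set.sum()),
                "n_background": int((~in_set).sum()),
                "set_effect": float(res.fixed_effects[coef_col]),
                "se": float(res.fixed_se[coef_col]),
                "wald_chi2": res.wald_chi2,
                "wald_df": res.wald_df,
                "p": res.p,
                "rho": res.rho,
                "var_between": res.var_between,
                "var_within": res.var_within,
            }
        )
    return pd.DataFrame(rows)


class SkewNormalRegression:
    """ML skew-normal regression: y = X beta + skew-normal(0, scale, shape).

    Because the direct parametrization's score in the shape parameter
    vanishes at shape = 0, the optimizer is started from the OLS solution at
    several shape values and the best likelihood wins.  ``fitted_mean``
    includes the skew-normal mean offset scale * delta * sqrt(2/pi),
    delta = shape / sqrt(1 + shape^2).
    """

    def __init__(self, shape_starts: Sequence[float] = (0.0, -3.0, 3.0), maxiter: int = 1000):
        self.shape_starts = tuple(shape_starts)
        self.maxiter = maxiter

    def get_params(self, deep: bool = True) -> dict:
        return {"shape_starts": self.shape_starts, "maxiter": self.maxiter}

    def set_params(self, **params) -> "SkewNormalRegression":
        for k, v in params.items():
            if k not in ("shape_starts", "maxiter"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SkewNormalRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, p) with matching y")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite (drop clipped/undefined values upstream)")
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta0
        sigma0 = float(np.std(resid))
        if sigma0 <= 0:
            raise ValueError("degenerate response: zero residual scale")

        p = X.shape[1]

        def nll(theta):
            beta = theta[:p]
            log_scale = theta[p]
            shape = theta[p + 1]
            scale = math.exp(log_scale)
            ll = stats.skewnorm.logpdf(y, a=shape, loc=X @ beta, scale=scale)
            val = -float(np.sum(ll))
            return val if np.isfinite(val) else 1e12

        best = None
        for a0 in self.shape_starts:
            # center the location start so loc + skew offset matches the OLS mean
            delta = a0 / math.sqrt(1.0 + a0 * a0)
            offset = sigma0 * delta * _SQRT_2_PI
            b = beta0.copy()
            b[0] -= offset  # assumes column 0 is the intercept
            theta0 = np.concatenate([b, [math.log(sigma0), a0]])
            res = optimize.minimize(
                nll, theta0, method="L-BFGS-B", options={"maxiter": self.maxiter}
            )
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None
        self.converged_ = bool(best.success)
        self.coef_ = best.x[:p]
        self.scale_ = float(math.exp(best.x[p]))
        self.shape_ = float(best.x[p + 1])
        self.loglik_ = -float(best.fun)
        return self

    def fitted_mean(self, X: np.ndarray) -> np.ndarray:
        delta = self.shape_ / math.sqrt(1.0 + self.shape_**2)
        return np.asarray(X, dtype=float) @ self.coef_ + self.scale_ * delta * _SQRT_2_PI


def skew_regress_z(
    z: np.ndarray, group: np.ndarray, min_group: int = 10
) -> SkewFit:
    """Skew-normal regression of Fisher-Z values on a 0/1 group indicator.

    Non-finite z values (clipped or undefined correlations) must be excluded
    by the caller; fitted group means on the Z scale are inverse-transformed
    to correlations via tanh.  Falls back to a normal-error regression
    (flagged) if the skew-normal fit does not converge.
    """
    z = np.asarray(z, dtype=float)
    group = np.asarray(group, dtype=int)
    if z.shape != group.shape:
        raise ValueError("z and group must align")
    if not np.all(np.isfinite(z)):
        raise ValueError("z contains non-finite values; exclude them upstream")
    n0 = int(np.sum(group == 0))
    n1 = int(np.sum(group == 1))
    if n0 < min_group or n1 < min_group:
        raise ValueError(f"each group needs >= {min_group} sites (got {n0}, {n1})")
    if np.ptp(z) == 0:
        raise ValueError("degenerate response: all z values identical")
    X = np.column_stack([np.ones_like(z), group.astype(float)])
    model = SkewNormalRegression()
    model.fit(X, z)
    fallback = False
    if not model.converged_:
        # normal-error fallback: shape pinned at 0
        model = SkewNormalRegression(shape_starts=(0.0,))
        model.fit(X, z)
        fallback = True
    mean0 = float(model.fitted_mean(np.array([[1.0, 0.0]]))[0])
    mean1 = float(model.fitted_mean(np.array([[1.0, 1.0]]))[0])
    # Wald p for the group coefficient from a numerical Hessian
    p_group = _wald_group_p(model, X, z)
    return SkewFit(
        coef=pd.Series(model.coef_, index=["intercept", "group"]),
        scale=model.scale_,
        shape=model.shape_,
        loglik=model.loglik_,
        group_mean_z={0: mean0, 1: mean1},
        group_r={0: math.tanh(mean0), 1: math.tanh(mean1)},
        group_diff_p=p_group,
        converged=model.converged_,
        normal_fallback=fallback,
    )


def _wald_group_p(model: SkewNormalRegression, X: np.ndarray, y: np.ndarray) -> Optional[float]:
    theta = np.concatenate([model.coef_, [math.log(model.scale_), model.shape_]])
    p = X.shape[1]

    def nll(t):
        ll = stats.skewnorm.logpdf(y, a=t[p + 1], loc=X @ t[:p], scale=math.exp(t[p]))
        val = -float(np.sum(ll))
        return val if np.isfinite(val) else 1e12

    try:
        hess = _numerical_hessian(nll, theta)
        cov = np.linalg.inv(hess)
        se = math.sqrt(max(cov[1, 1], 0.0))
        if se == 0:
            return None
        zstat = model.coef_[1] / se
        return float(2.0 * stats.norm.sf(abs(zstat)))
    except np.linalg.LinAlgError:
        return None


def _numerical_hessian(f, x0: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x0.size
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            hess[i, j] = hess[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4.0 * eps * eps)
    return hess
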