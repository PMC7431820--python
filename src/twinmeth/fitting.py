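"""Per-site maximum-likelihood estimation of the twin model variants.

Five variants are fitted per CpG: the full bivariate ACE and ADE Cholesky
models and the nested AE, CE and E submodels.  Estimation maximises the FIML
log-likelihood (see :mod:`twinmeth.kernel`) with L-BFGS-B over a bounded
parameterization (diagonal Cholesky paths >= 0, cohort scalars > 0) from a
moment-based start plus random restarts.  Model comparison uses AIC between
ACE and ADE (ties retain ADE) and naive likelihood-ratio chi-square tests
against nested submodels with degrees of freedom equal to the difference in
free-parameter counts — no boundary-mixture correction by default, matching
the conventional reporting of such twin analyses (a mixture option exists but
is off by default).

Sites whose model-implied moments fall outside the plausible M-value range
(mean outside [-6.25, 6.25] or SD above 1.5 under either full variant at
either occasion) are flagged for exclusion.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .kernel import AGE_CENTER, PathParameters, build_pair_cov
from .records import TwinPairRecord

__all__ = [
    "VARIANTS",
    "FitSettings",
    "FitResult",
    "SiteTests",
    "FilterFlag",
    "TwinCholeskyModel",
    "fit_variant",
    "lrt",
    "stability_test",
    "select_best",
    "filter_site",
    "run_methylome",
]

VARIANTS = ("ACE", "ADE", "AE", "CE", "E")

#: Post-fit probe-filter thresholds on the M-value scale.
MEAN_BOUND = 6.25
SD_BOUND = 1.5

_LOG_2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1e12

_NESTED_WITHIN = {
    "ACE": {"AE", "CE", "E"},
    "ADE": {"AE", "E"},
    "AE": {"E"},
    "CE": {"E"},
}

_PATH_NAMES = {
    "ACE": ("a11", "a21", "a22", "s11", "s21", "s22", "e11", "e21", "e22"),
    "ADE": ("a11", "a21", "a22", "s11", "s21", "s22", "e11", "e21", "e22"),
    "AE": ("a11", "a21", "a22", "e11", "e21", "e22"),
    "CE": ("s11", "s21", "s22", "e11", "e21", "e22"),
    "E": ("e11", "e21", "e22"),
}

_SECOND_SOURCE = {"ACE": "C", "ADE": "D", "AE": "C", "CE": "C", "E": "C"}
_CROSS_PATHS = ("a21", "s21", "e21")


@dataclass(frozen=True)
class FitSettings:
    """Optimizer and pipeline settings.

    ``n_restarts`` random restarts are attempted in addition to the
    moment-based start (and any warm starts supplied by the caller).
    """

    n_restarts: int = 2
    seed: int = 0
    maxiter: int = 500
    gtol: float = 1e-8
    occasion_specific_covariates: bool = False
    raw_moment_filter: bool = False
    boundary_mixture: bool = False


@dataclass
class FitResult:
    """One converged (or flagged) maximum-likelihood fit at one site."""

    variant: str
    params: PathParameters
    loglik: float
    n_free: int
    aic: float
    converged: bool
    n_pairs_used: int

    def __post_init__(self) -> None:
        expected = -2.0 * self.loglik + 2.0 * self.n_free
        if not math.isclose(self.aic, expected, rel_tol=0.0, abs_tol=1e-9):
            raise ValueError("aic inconsistent with loglik and n_free")


@dataclass
class SiteTests:
    """Likelihood-ratio tests reported per site (on the best variant)."""

    chi2_full_vs_E: float = np.nan
    df_full_vs_E: int = 6
    p_full_vs_E: float = np.nan
    chi2_AE_vs_E: float = np.nan
    df_AE_vs_E: int = 3
    p_AE_vs_E: float = np.nan
    chi2_stability: float = np.nan
    df_stability: int = 3
    p_stability: float = np.nan


@dataclass
class FilterFlag:
    """Post-fit probe-filter outcome."""

    mean_out_of_range: bool
    sd_out_of_range: bool

    @property
    def keep(self) -> bool:
        return not (self.mean_out_of_range or self.sd_out_of_range)


# ---------------------------------------------------------------------------
# compiled site data: observations grouped by (zygosity, country, mask)

_SHARED_MEANS = ("beta0_t1", "beta0_t2", "beta_age", "beta_sex", "beta_country")
_OCCSPEC_MEANS = (
    "beta0_t1",
    "beta0_t2",
    "beta_age_t1",
    "beta_age_t2",
    "beta_sex_t1",
    "beta_sex_t2",
    "beta_country_t1",
    "beta_country_t2",
)


def _slot_design(rec: TwinPairRecord, occasion_specific: bool) -> np.ndarray:
    """(4, P) design matrix of the mean model in slot order."""
    ages = np.array([rec.age_t1, rec.age_t2, rec.age_t1, rec.age_t2]) - AGE_CENTER
    is1 = np.array([1.0, 0.0, 1.0, 0.0])
    is2 = 1.0 - is1
    sex = float(rec.sex)
    cty = float(rec.country)
    if not occasion_specific:
        cols = [is1, is2, ages, np.full(4, sex), np.full(4, cty)]
    else:
        cols = [
            is1,
            is2,
            ages * is1,
            ages * is2,
            sex * is1,
            sex * is2,
            cty * is1,
            cty * is2,
        ]
    return np.column_stack(cols)


@dataclass
class _Group:
    zygosity: str
    country: int
    idx: np.ndarray  # observed slot indices
    Y: np.ndarray  # (n, m) observations
    X: np.ndarray  # (n, m, P) mean design
    pair_ids: list[str]

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def m(self) -> int:
        return self.Y.shape[1]


@dataclass
class _CompiledSite:
    groups: list[_Group]
    n_pairs: int
    sex_varies: bool
    country_varies: bool
    has_country1: bool
    occasion_specific: bool
    mean_names: tuple[str, ...]

    @classmethod
    def build(cls, records: Sequence[TwinPairRecord], occasion_specific: bool):
        if len(records) < 2:
            raise ValueError("at least 2 pair records are required")
        buckets: dict[tuple, list[TwinPairRecord]] = {}
        for rec in records:
            key = (rec.zygosity, rec.country, tuple(bool(b) for b in rec.mask))
            buckets.setdefault(key, []).append(rec)
        groups = []
        for (zyg, cty, mask), recs in sorted(buckets.items()):
            idx = np.flatnonzero(np.array(mask))
            Y = np.array([r.y[idx] for r in recs])
            X = np.array([_slot_design(r, occasion_specific)[idx] for r in recs])
            groups.append(_Group(zyg, cty, idx, Y, X, [r.pair_id for r in recs]))
        sexes = {r.sex for r in records}
        countries = {r.country for r in records}
        return cls(
            groups=groups,
            n_pairs=len(records),
            sex_varies=len(sexes) > 1,
            country_varies=len(countries) > 1,
            has_country1=1 in countries,
            occasion_specific=occasion_specific,
            mean_names=_OCCSPEC_MEANS if occasion_specific else _SHARED_MEANS,
        )


# ---------------------------------------------------------------------------
# parameter layout: names <-> flat optimizer vector


@dataclass
class _Layout:
    variant: str
    path_names: tuple[str, ...]
    free_k: bool
    mean_free: tuple[bool, ...]  # which canonical mean columns are free
    occasion_specific: bool

    @classmethod
    def build(cls, variant: str, site: _CompiledSite, fix_cross: bool = False):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        paths = _PATH_NAMES[variant]
        if fix_cross:
            paths = tuple(p for p in paths if p not in _CROSS_PATHS)
        free = []
        for name in site.mean_names:
            if name.startswith("beta_sex"):
                free.append(site.sex_varies)
            elif name.startswith("beta_country"):
                free.append(site.country_varies)
            else:
                free.append(True)
        return cls(
            variant=variant,
            path_names=paths,
            free_k=site.has_country1,
            mean_free=tuple(free),
            occasion_specific=site.occasion_specific,
        )

    @property
    def n_paths(self) -> int:
        return len(self.path_names)

    @property
    def n_means(self) -> int:
        return sum(self.mean_free)

    @property
    def size(self) -> int:
        return self.n_paths + (2 if self.free_k else 0) + self.n_means

    def bounds(self) -> list[tuple]:
        out: list[tuple] = []
        for name in self.path_names:
            # diagonal paths carry the >= 0 sign convention; a tiny floor on
            # the E diagonals keeps the covariance invertible
            if name in ("e11", "e22"):
                out.append((1e-6, None))
            elif name.endswith("11") or name.endswith("22"):
                out.append((0.0, None))
            else:
                out.append((None, None))
        if self.free_k:
            out.extend([(1e-3, 1e3), (1e-3, 1e3)])
        out.extend([(None, None)] * self.n_means)
        return out

    def unpack_batch(self, xb: np.ndarray):
        """Vectorized unpack of a (K, size) batch of parameter vectors.

        -> (paths dict of (K,) arrays, k1 (K,), k2 (K,), beta (K, P)).
        """
        K = xb.shape[0]
        paths = {
            name: np.zeros(K)
            for name in ("a11", "a21", "a22", "s11", "s21", "s22", "e11", "e21", "e22")
        }
        for j, name in enumerate(self.path_names):
            paths[name] = xb[:, j]
        pos = self.n_paths
        if self.free_k:
            k1, k2 = xb[:, pos], xb[:, pos + 1]
            pos += 2
        else:
            k1 = k2 = np.ones(K)
        names = _OCCSPEC_MEANS if self.occasion_specific else _SHARED_MEANS
        beta = np.zeros((K, len(names)))
        for j, is_free in enumerate(self.mean_free):
            if is_free:
                beta[:, j] = xb[:, pos]
                pos += 1
        return paths, k1, k2, beta

    def unpack(self, x: np.ndarray):
        """-> (paths dict, k1, k2, full-beta over canonical mean columns)."""
        paths = dict.fromkeys(
            ("a11", "a21", "a22", "s11", "s21", "s22", "e11", "e21", "e22"), 0.0
        )
        for name, val in zip(self.path_names, x[: self.n_paths]):
            paths[name] = float(val)
        pos = self.n_paths
        if self.free_k:
            k1, k2 = float(x[pos]), float(x[pos + 1])
            pos += 2
        else:
            k1 = k2 = 1.0
        names = _OCCSPEC_MEANS if self.occasion_specific else _SHARED_MEANS
        beta = np.zeros(len(names))
        for j, is_free in enumerate(self.mean_free):
            if is_free:
                beta[j] = x[pos]
                pos += 1
        return paths, k1, k2, beta

    def pack(self, params: PathParameters) -> np.ndarray:
        """Project a PathParameters object onto this layout's free vector."""
        x = []
        for name in self.path_names:
            x.append(getattr(params, name))
        if self.free_k:
            x.extend([params.k1, params.k2])
        if self.occasion_specific:
            vals = {
                "beta0_t1": params.beta0_t1,
                "beta0_t2": params.beta0_t2,
                "beta_age_t1": params.beta_age,
                "beta_age_t2": params.beta_age
                if params.beta_age_t2 is None
                else params.beta_age_t2,
                "beta_sex_t1": params.beta_sex,
                "beta_sex_t2": params.beta_sex
                if params.beta_sex_t2 is None
                else params.beta_sex_t2,
                "beta_country_t1": params.beta_country,
                "beta_country_t2": params.beta_country
                if params.beta_country_t2 is None
                else params.beta_country_t2,
            }
            names = _OCCSPEC_MEANS
        else:
            vals = {
                "beta0_t1": params.beta0_t1,
                "beta0_t2": params.beta0_t2,
                "beta_age": params.beta_age,
                "beta_sex": params.beta_sex,
                "beta_country": params.beta_country,
            }
            names = _SHARED_MEANS
        for name, is_free in zip(names, self.mean_free):
            if is_free:
                x.append(vals[name])
        return np.array(x, dtype=float)

    def to_params(self, x: np.ndarray) -> PathParameters:
        paths, k1, k2, beta = self.unpack(x)
        names = _OCCSPEC_MEANS if self.occasion_specific else _SHARED_MEANS
        b = dict(zip(names, beta))
        kwargs = dict(
            second_source=_SECOND_SOURCE[self.variant],
            k1=k1,
            k2=k2,
            **paths,
        )
        if self.occasion_specific:
            kwargs.update(
                beta0_t1=b["beta0_t1"],
                beta0_t2=b["beta0_t2"],
                beta_age=b["beta_age_t1"],
                beta_age_t2=b["beta_age_t2"],
                beta_sex=b["beta_sex_t1"],
                beta_sex_t2=b["beta_sex_t2"],
                beta_country=b["beta_country_t1"],
                beta_country_t2=b["beta_country_t2"],
            )
        else:
            kwargs.update(
                beta0_t1=b["beta0_t1"],
                beta0_t2=b["beta0_t2"],
                beta_age=b["beta_age"],
                beta_sex=b["beta_sex"],
                beta_country=b["beta_country"],
            )
        return PathParameters(**kwargs)


# ---------------------------------------------------------------------------
# vectorized negative log-likelihood


def _neg_loglik(x: np.ndarray, layout: _Layout, site: _CompiledSite) -> float:
    paths, k1, k2, beta = layout.unpack(x)
    a = (paths["a11"], paths["a21"], paths["a22"])
    s = (paths["s11"], paths["s21"], paths["s22"])
    e = (paths["e11"], paths["e21"], paths["e22"])
    src = _SECOND_SOURCE[layout.variant]
    total = 0.0
    covs: dict[tuple, np.ndarray] = {}
    for g in site.groups:
        key = (g.zygosity, g.country)
        sigma = covs.get(key)
        if sigma is None:
            sigma = build_pair_cov(a, s, e, src, g.zygosity, g.country, k1, k2)
            covs[key] = sigma
        sub = sigma[np.ix_(g.idx, g.idx)]
        try:
            chol = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return _PENALTY
        mu = g.X @ beta
        resid = g.Y - mu
        z = solve_triangular(chol, resid.T, lower=True, check_finite=False)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        total += -0.5 * (g.m * _LOG_2PI + logdet) * g.n - 0.5 * float(np.sum(z * z))
    if not np.isfinite(total):
        return _PENALTY
    return -total


def _batched_neg_loglik(xb: np.ndarray, layout: _Layout, site: _CompiledSite) -> np.ndarray:
    """Negative log-likelihood at K parameter vectors simultaneously.

    The batch dimension rides through numpy's stacked linalg (one batched
    Cholesky/solve per observation group), which is what makes the
    finite-difference gradient cheap.
    """
    K = xb.shape[0]
    paths, k1, k2, beta = layout.unpack_batch(xb)

    def comp(l11, l21, l22):
        c = np.empty((K, 2, 2))
        c[:, 0, 0] = l11 * l11
        c[:, 0, 1] = c[:, 1, 0] = l11 * l21
        c[:, 1, 1] = l21 * l21 + l22 * l22
        return c

    A = comp(paths["a11"], paths["a21"], paths["a22"])
    S = comp(paths["s11"], paths["s21"], paths["s22"])
    E = comp(paths["e11"], paths["e21"], paths["e22"])
    W = A + S + E
    src = _SECOND_SOURCE[layout.variant]
    out = np.zeros(K)
    cache: dict[tuple, np.ndarray] = {}
    for g in site.groups:
        key = (g.zygosity, g.country)
        sigma = cache.get(key)
        if sigma is None:
            alpha_a = 1.0 if g.zygosity == "MZ" else 0.5
            alpha_s = 1.0 if src == "C" or g.zygosity == "MZ" else 0.25
            cross = alpha_a * A + alpha_s * S
            sigma = np.empty((K, 4, 4))
            sigma[:, :2, :2] = W
            sigma[:, 2:, 2:] = W
            sigma[:, :2, 2:] = cross
            sigma[:, 2:, :2] = cross
            if g.country == 1:
                v = np.stack([k1, k2, k1, k2], axis=1)
                sigma = sigma * (v[:, :, None] * v[:, None, :])
            cache[key] = sigma
        sub = sigma[:, g.idx][:, :, g.idx]
        mu = np.einsum("nmp,kp->knm", g.X, beta)
        resid = (g.Y[None, :, :] - mu).transpose(0, 2, 1)  # (K, m, n)
        try:
            chol = np.linalg.cholesky(sub)
            sol = np.linalg.solve(sub, resid)
        except np.linalg.LinAlgError:
            # rare (near-)singular corner: fall back to scalar evaluation with
            # per-vector penalties
            return np.array([_neg_loglik(xb[i], layout, site) for i in range(K)])
        logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
        quad = np.sum(resid * sol, axis=(1, 2))
        out += -0.5 * (g.m * _LOG_2PI + logdet) * g.n - 0.5 * quad
    out = np.where(np.isfinite(out), out, -_PENALTY)
    return -out


def _value_and_grad(x: np.ndarray, layout: _Layout, site: _CompiledSite, upper: np.ndarray):
    """Objective and forward-difference gradient in one batched evaluation."""
    n = x.size
    h = 1.5e-7 * np.maximum(1.0, np.abs(x))
    sign = np.where(x + h > upper, -1.0, 1.0)
    xb = np.tile(x, (n + 1, 1))
    xb[1:] += np.diag(h * sign)
    vals = _batched_neg_loglik(xb, layout, site)
    grad = (vals[1:] - vals[0]) / (h * sign)
    return float(vals[0]), grad


# ---------------------------------------------------------------------------
# starting values


def _moment_start(site: _CompiledSite, layout: _Layout) -> np.ndarray:
    """Moment-based start: OLS means, Falconer-style variance allocation."""
    # OLS of observed values on the slot design
    Xs = np.concatenate([g.X.reshape(-1, g.X.shape[2]) for g in site.groups])
    ys = np.concatenate([g.Y.ravel() for g in site.groups])
    free = np.array(layout.mean_free)
    beta_full = np.zeros(Xs.shape[1])
    coef, *_ = np.linalg.lstsq(Xs[:, free], ys, rcond=None)
    beta_full[free] = coef

    # residuals laid back onto 4-slot frames
    var1: list[float] = []
    var2: list[float] = []
    cross: dict[tuple[str, int], list[float]] = {}
    within: list[float] = []
    k_num = {1: [], 2: []}
    for g in site.groups:
        resid = g.Y - g.X @ beta_full
        full = np.full((g.n, 4), np.nan)
        full[:, g.idx] = resid
        scale = 1.0
        for t, slots in ((1, (0, 2)), (2, (1, 3))):
            vals = full[:, slots][~np.isnan(full[:, slots])]
            if g.country == 1 and vals.size:
                k_num[t].extend((vals**2).tolist())
            elif vals.size:
                (var1 if t == 1 else var2).extend((vals**2).tolist())
        prod11 = full[:, 0] * full[:, 2]
        prod22 = full[:, 1] * full[:, 3]
        # country-1 products are pooled unscaled; this only seeds the optimizer
        for t, prod in ((1, prod11), (2, prod22)):
            vals = prod[~np.isnan(prod)]
            if vals.size:
                cross.setdefault((g.zygosity, t), []).extend(vals.tolist())
        w = full[:, 0] * full[:, 1]
        w2 = full[:, 2] * full[:, 3]
        within.extend(w[~np.isnan(w)].tolist())
        within.extend(w2[~np.isnan(w2)].tolist())

    V1 = float(np.mean(var1)) if var1 else 1.0
    V2 = float(np.mean(var2)) if var2 else 1.0
    V1 = max(V1, 1e-6)
    V2 = max(V2, 1e-6)
    k1 = math.sqrt(max(np.mean(k_num[1]), 1e-8) / V1) if k_num[1] else 0.9
    k2 = math.sqrt(max(np.mean(k_num[2]), 1e-8) / V2) if k_num[2] else 0.9

    def cmean(key, default=0.0):
        vals = cross.get(key, [])
        return float(np.mean(vals)) if vals else default

    P12 = float(np.mean(within)) if within else 0.0
    P12 = float(np.clip(P12, -0.9 * math.sqrt(V1 * V2), 0.9 * math.sqrt(V1 * V2)))

    shares = {}
    for t, V in ((1, V1), (2, V2)):
        mz = cmean(("MZ", t))
        dz = cmean(("DZ", t))
        if layout.variant in ("ACE", "AE"):
            A = 2.0 * (mz - dz)
            S = 2.0 * dz - mz
        elif layout.variant == "ADE":
            A = 4.0 * dz - mz
            S = 2.0 * mz - 4.0 * dz
        elif layout.variant == "CE":
            A = 0.0
            S = dz
        else:  # E
            A = 0.0
            S = 0.0
        if layout.variant == "AE":
            A = max(mz, A)
            S = 0.0
        A = float(np.clip(A, 0.0, 0.9 * V))
        S = float(np.clip(S, 0.0, 0.9 * V - A))
        E = max(V - A - S, 0.05 * V)
        shares[t] = (A, S, E)

    def paths_for(v1: float, v2: float, share: float):
        l11 = math.sqrt(max(v1, 1e-8))
        c12 = share * P12
        l21 = float(np.clip(c12 / l11, -0.95 * math.sqrt(max(v2, 1e-8)), 0.95 * math.sqrt(max(v2, 1e-8))))
        l22 = math.sqrt(max(v2 - l21 * l21, 0.05 * max(v2, 1e-8)))
        return l11, l21, l22

    A1, S1, E1 = shares[1]
    A2, S2, E2 = shares[2]
    tot1 = max(A1 + S1 + E1, 1e-8)
    p = PathParameters(second_source=_SECOND_SOURCE[layout.variant], k1=k1, k2=k2)
    vals = {}
    vals["a11"], vals["a21"], vals["a22"] = paths_for(A1, A2, A1 / tot1)
    vals["s11"], vals["s21"], vals["s22"] = paths_for(S1, S2, S1 / tot1)
    vals["e11"], vals["e21"], vals["e22"] = paths_for(E1, E2, E1 / tot1)
    p = p.replace(**vals)
    names = _OCCSPEC_MEANS if site.occasion_specific else _SHARED_MEANS
    b = dict(zip(names, beta_full))
    if site.occasion_specific:
        p = p.replace(
            beta0_t1=b["beta0_t1"],
            beta0_t2=b["beta0_t2"],
            beta_age=b["beta_age_t1"],
            beta_age_t2=b["beta_age_t2"],
            beta_sex=b["beta_sex_t1"],
            beta_sex_t2=b["beta_sex_t2"],
            beta_country=b["beta_country_t1"],
            beta_country_t2=b["beta_country_t2"],
        )
    else:
        p = p.replace(
            beta0_t1=b["beta0_t1"],
            beta0_t2=b["beta0_t2"],
            beta_age=b["beta_age"],
            beta_sex=b["beta_sex"],
            beta_country=b["beta_country"],
        )
    return layout.pack(p)


def _clip_to_bounds(x: np.ndarray, bounds: list[tuple]) -> np.ndarray:
    out = x.copy()
    for j, (lo, hi) in enumerate(bounds):
        if lo is not None:
            out[j] = max(out[j], lo)
        if hi is not None:
            out[j] = min(out[j], hi)
    return out


# ---------------------------------------------------------------------------
# estimator


class TwinCholeskyModel:
    """Maximum-likelihood bivariate Cholesky twin model for one CpG site.

    Estimator-style interface: construct with hyperparameters, call
    :meth:`fit` with a sequence of :class:`TwinPairRecord`, then read fitted
    attributes (``params_``, ``loglik_``, ``aic_``, ``n_free_``,
    ``converged_``, ``n_pairs_``, ``result_``).

    Parameters
    ----------
    variant : {"ACE", "ADE", "AE", "CE", "E"}
    n_restarts : int
        Random restarts in addition to the moment start.
    seed : int
        Seed for restart perturbations (fits are deterministic given it).
    maxiter : int
        L-BFGS-B iteration cap per start.
    occasion_specific_covariates : bool
        If True, age/sex/country slopes are estimated per occasion instead of
        shared across occasions.
    fix_cross_paths : bool
        If True, the three cross-occasion paths are fixed at zero (the
        stability-constrained model).
    """

    def __init__(
        self,
        variant: str = "ADE",
        n_restarts: int = 2,
        seed: int = 0,
        maxiter: int = 500,
        gtol: float = 1e-8,
        occasion_specific_covariates: bool = False,
        fix_cross_paths: bool = False,
    ):
        self.variant = variant
        self.n_restarts = n_restarts
        self.seed = seed
        self.maxiter = maxiter
        self.gtol = gtol
        self.occasion_specific_covariates = occasion_specific_covariates
        self.fix_cross_paths = fix_cross_paths

    _param_names = (
        "variant",
        "n_restarts",
        "seed",
        "maxiter",
        "gtol",
        "occasion_specific_covariates",
        "fix_cross_paths",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "TwinCholeskyModel":
        for name, value in params.items():
            if name not in self._param_names:
                raise ValueError(f"unknown parameter {name!r}")
            setattr(self, name, value)
        return self

    def fit(
        self,
        records: Sequence[TwinPairRecord],
        warm_starts: Sequence[PathParameters] = (),
    ) -> "TwinCholeskyModel":
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        records = list(records)
        site = _CompiledSite.build(records, self.occasion_specific_covariates)
        layout = _Layout.build(self.variant, site, fix_cross=self.fix_cross_paths)
        bounds = layout.bounds()
        rng = np.random.default_rng(self.seed)

        starts = [_moment_start(site, layout)]
        for wp in warm_starts:
            starts.append(layout.pack(wp))
        base = starts[0]
        scale = np.maximum(np.abs(base), 0.1)
        for _ in range(self.n_restarts):
            starts.append(base + scale * rng.normal(0.0, 0.4, size=base.size))
        starts = [_clip_to_bounds(x0, bounds) for x0 in starts]

        upper = np.array([np.inf if b[1] is None else b[1] for b in bounds])
        runs = []
        for x0 in starts:
            res = optimize.minimize(
                _value_and_grad,
                x0,
                args=(layout, site, upper),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.maxiter, "gtol": self.gtol, "ftol": 1e-12},
            )
            if np.isfinite(res.fun) and res.fun < _PENALTY / 2:
                runs.append(res)
        if not runs:
            raise RuntimeError(f"no start produced a finite likelihood ({self.variant})")
        best = min(runs, key=lambda r: r.fun)
        best_success = any(r.success and r.fun <= best.fun + 1e-6 for r in runs)

        self.params_ = layout.to_params(best.x)
        self.loglik_ = -float(best.fun)
        self.n_free_ = layout.size
        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.n_free_
        self.converged_ = best_success
        self.n_pairs_ = site.n_pairs
        self.result_ = FitResult(
            variant=self.variant,
            params=self.params_,
            loglik=self.loglik_,
            n_free=self.n_free_,
            aic=self.aic_,
            converged=self.converged_,
            n_pairs_used=self.n_pairs_,
        )
        return self


def fit_variant(
    records: Sequence[TwinPairRecord],
    variant: str,
    settings: FitSettings = FitSettings(),
    warm_starts: Sequence[PathParameters] = (),
) -> FitResult:
    """Fit one model variant to one site's records (thin estimator wrapper)."""
    model = TwinCholeskyModel(
        variant=variant,
        n_restarts=settings.n_restarts,
        seed=settings.seed,
        maxiter=settings.maxiter,
        gtol=settings.gtol,
        occasion_specific_covariates=settings.occasion_specific_covariates,
    )
    model.fit(records, warm_starts=warm_starts)
    return model.result_


#: boundary-constrained (variance-like) parameters dropped in each nesting,
#: used only by the optional chi-bar-square reference
_N_BOUNDARY = {
    ("ACE", "E"): 4, ("ADE", "E"): 4,
    ("ACE", "AE"): 2, ("ADE", "AE"): 2, ("ACE", "CE"): 2,
    ("AE", "E"): 2, ("CE", "E"): 2,
}


def chi_bar_square_sf(chi2: float, n_boundary: int, n_free: int) -> float:
    """Upper-tail probability under an equal-binomial-weights chi-bar-square.

    Approximates the LRT null when ``n_boundary`` of the tested parameters
    are variances constrained to zero from inside the boundary and
    ``n_free`` are unconstrained: a 2^-b binomial mixture of chi-squares
    with df from n_free to n_free + n_boundary (independence approximation).
    """
    if n_boundary == 0:
        return float(stats.chi2.sf(chi2, n_free))
    p = 0.0
    for j in range(n_boundary + 1):
        w = math.comb(n_boundary, j) / 2.0**n_boundary
        df_j = n_free + j
        tail = float(stats.chi2.sf(chi2, df_j)) if df_j > 0 else float(chi2 <= 0)
        p += w * tail
    return p


def lrt(
    full: FitResult, nested: FitResult, boundary_mixture: bool = False
) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested variant against a fuller one.

    chi2 = 2 (ll_full - ll_nested), clipped at zero; df is the difference in
    free-parameter counts; p is the naive upper-tail chi-square probability
    (the conventional reporting), or the chi-bar-square approximation when
    ``boundary_mixture`` is set.
    """
    if nested.variant not in _NESTED_WITHIN.get(full.variant, set()):
        raise ValueError(f"{nested.variant} is not nested within {full.variant}")
    df = full.n_free - nested.n_free
    chi2 = 2.0 * (full.loglik - nested.loglik)
    if chi2 < -1e-6:
        raise ValueError("nested log-likelihood exceeds the full model's")
    chi2 = max(chi2, 0.0)
    if boundary_mixture:
        b = _N_BOUNDARY.get((full.variant, nested.variant), 0)
        p = chi_bar_square_sf(chi2, b, df - b)
    else:
        p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def stability_test(
    best: FitResult,
    records: Sequence[TwinPairRecord],
    settings: FitSettings = FitSettings(),
) -> tuple[float, int, float, FitResult]:
    """Cross-time stability test: refit with a21 = s21 = e21 = 0, LRT df = 3.

    A significant result indicates cross-occasion association (stability) via
    at least one of the sources; the constrained fit is warm-started from the
    unconstrained solution with its cross paths zeroed.
    """
    zeroed = best.params.replace(a21=0.0, s21=0.0, e21=0.0)
    model = TwinCholeskyModel(
        variant=best.variant,
        n_restarts=settings.n_restarts,
        seed=settings.seed,
        maxiter=settings.maxiter,
        gtol=settings.gtol,
        occasion_specific_covariates=settings.occasion_specific_covariates,
        fix_cross_paths=True,
    )
    model.fit(records, warm_starts=[zeroed])
    constrained = model.result_
    df = best.n_free - constrained.n_free
    chi2 = max(2.0 * (best.loglik - constrained.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p, constrained


def select_best(
    ace: Optional[FitResult], ade: Optional[FitResult]
) -> Optional[FitResult]:
    """Retain ADE if its AIC is as good or better than ACE's; else ACE.

    Non-converged fits lose to converged ones; if neither converged the site
    is flagged by returning None.
    """
    ace_ok = ace is not None and ace.converged
    ade_ok = ade is not None and ade.converged
    if ade_ok and ace_ok:
        return ade if ade.aic <= ace.aic else ace
    if ade_ok:
        return ade
    if ace_ok:
        return ace
    return None


def _implied_moments(fit: FitResult, mean_sex: float) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied (mean, SD) per occasion at reference covariates.

    Reference: age 74 (centered zero), sex at the sample mean, country 0
    (reference cohort scale).
    """
    p = fit.params
    means = np.array(
        [
            p.occasion_mean(1, AGE_CENTER, 0, 0) + p.beta_sex * mean_sex,
            p.occasion_mean(2, AGE_CENTER, 0, 0)
            + (p.beta_sex if p.beta_sex_t2 is None else p.beta_sex_t2) * mean_sex,
        ]
    )
    v1 = p.a11**2 + p.s11**2 + p.e11**2
    v2 = (p.a21**2 + p.a22**2) + (p.s21**2 + p.s22**2) + (p.e21**2 + p.e22**2)
    return means, np.sqrt(np.array([v1, v2]))


def filter_site(
    ace: FitResult,
    ade: FitResult,
    records: Sequence[TwinPairRecord],
    raw_moments: bool = False,
) -> FilterFlag:
    """Flag sites whose implied M-value moments are out of range.

    Mean outside [-6.25, 6.25] or SD strictly exceeding 1.5 under *either*
    full variant at *either* occasion flags the site.  With
    ``raw_moments=True`` the sample mean/SD per occasion are used instead of
    model-implied moments.
    """
    if raw_moments:
        vals = {1: [], 2: []}
        for rec in records:
            for slot, occ in enumerate((1, 2, 1, 2)):
                if rec.mask[slot]:
                    vals[occ].append(rec.y[slot])
        means = np.array([np.mean(vals[1]), np.mean(vals[2])])
        sds = np.array([np.std(vals[1], ddof=1), np.std(vals[2], ddof=1)])
        mean_bad = bool(np.any(np.abs(means) > MEAN_BOUND))
        sd_bad = bool(np.any(sds > SD_BOUND))
        return FilterFlag(mean_bad, sd_bad)
    mean_sex = float(np.mean([r.sex for r in records]))
    mean_bad = False
    sd_bad = False
    for fit in (ace, ade):
        means, sds = _implied_moments(fit, mean_sex)
        mean_bad = mean_bad or bool(np.any(np.abs(means) > MEAN_BOUND))
        sd_bad = sd_bad or bool(np.any(sds > SD_BOUND))
    return FilterFlag(mean_bad, sd_bad)


# ---------------------------------------------------------------------------
# methylome-scale driver


def _site_seed(master_seed: int, site_id: str) -> int:
    """Stable per-site restart seed derived from the master seed."""
    digest = zlib.crc32(site_id.encode("utf-8"))
    return int(np.random.SeedSequence([master_seed, digest]).generate_state(1)[0] % (2**31))


def run_methylome(
    dataset: Mapping[str, Sequence[TwinPairRecord]],
    settings: FitSettings = FitSettings(),
    variants: Sequence[str] = VARIANTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit all variants at every site; returns (results, failures).

    Deterministic given ``settings.seed``: each site's restart seed is derived
    from the master seed and the site id.  Per-site failures are recorded and
    the run continues.
    """
    from . import estimates  # deferred: estimates imports FitResult from here

    rows = []
    failures = []
    for site_id in sorted(dataset):
        records = list(dataset[site_id])
        try:
            site_settings = replace(settings, seed=_site_seed(settings.seed, site_id))
            rows.extend(_fit_site(site_id, records, site_settings, variants, estimates))
        except Exception as exc:  # noqa: BLE001 - per-site failures must not kill the run
            failures.append({"site_id": site_id, "error": f"{type(exc).__name__}: {exc}"})
    results = pd.DataFrame(rows)
    return results, pd.DataFrame(failures, columns=["site_id", "error"])


def _fit_site(site_id, records, settings, variants, estimates):
    fits: dict[str, FitResult] = {}
    fits["ACE"] = fit_variant(records, "ACE", settings) if "ACE" in variants else None
    fits["ADE"] = fit_variant(records, "ADE", settings) if "ADE" in variants else None
    warm_ae = []
    for v in ("ACE", "ADE"):
        if fits.get(v):
            warm_ae.append(fits[v].params.replace(s11=0.0, s21=0.0, s22=0.0))
    if "AE" in variants:
        fits["AE"] = fit_variant(records, "AE", settings, warm_starts=warm_ae)
    if "CE" in variants and fits.get("ACE"):
        fits["CE"] = fit_variant(
            records,
            "CE",
            settings,
            warm_starts=[fits["ACE"].params.replace(a11=0.0, a21=0.0, a22=0.0)],
        )
    elif "CE" in variants:
        fits["CE"] = fit_variant(records, "CE", settings)
    if "E" in variants:
        warm_e = [f.params.replace(a11=0, a21=0, a22=0, s11=0, s21=0, s22=0)
                  for f in fits.values() if f is not None]
        fits["E"] = fit_variant(records, "E", settings, warm_starts=warm_e)

    best = select_best(fits.get("ACE"), fits.get("ADE"))
    tests = SiteTests()
    constrained = None
    if best is not None and fits.get("E"):
        tests.chi2_full_vs_E, tests.df_full_vs_E, tests.p_full_vs_E = lrt(
            best, fits["E"], boundary_mixture=settings.boundary_mixture
        )
    if fits.get("AE") and fits.get("E"):
        tests.chi2_AE_vs_E, tests.df_AE_vs_E, tests.p_AE_vs_E = lrt(
            fits["AE"], fits["E"], boundary_mixture=settings.boundary_mixture
        )
    if best is not None:
        try:
            (
                tests.chi2_stability,
                tests.df_stability,
                tests.p_stability,
                constrained,
            ) = stability_test(best, records, settings)
        except RuntimeError:
            pass  # flagged missing p (NaN)
    if fits.get("ACE") and fits.get("ADE"):
        flag = filter_site(
            fits["ACE"], fits["ADE"], records, raw_moments=settings.raw_moment_filter
        )
    else:
        flag = FilterFlag(False, False)

    rows = []
    for variant in variants:
        fit = fits.get(variant)
        if fit is None:
            continue
        comp = estimates.standardize(fit)
        corr = estimates.cross_time_correlations(fit)
        p = fit.params
        row = {
            "site_id": site_id,
            "variant": variant,
            "best": best is not None and variant == best.variant,
            "best_variant": best.variant if best is not None else "",
            "converged": fit.converged,
            "n_pairs_used": fit.n_pairs_used,
            "loglik": fit.loglik,
            "n_free": fit.n_free,
            "aic": fit.aic,
            "a11": p.a11, "a21": p.a21, "a22": p.a22,
            "s11": p.s11, "s21": p.s21, "s22": p.s22,
            "e11": p.e11, "e21": p.e21, "e22": p.e22,
            "second_source": p.second_source,
            "k1": p.k1, "k2": p.k2,
            "beta0_t1": p.beta0_t1, "beta0_t2": p.beta0_t2,
            "beta_age": p.beta_age, "beta_sex": p.beta_sex,
            "beta_country": p.beta_country,
            "total_var_1": comp.total_var_1, "total_var_2": comp.total_var_2,
            "sd_1": math.sqrt(comp.total_var_1), "sd_2": math.sqrt(comp.total_var_2),
            "abs_A_1": comp.abs_A_1, "abs_CD_1": comp.abs_CD_1, "abs_E_1": comp.abs_E_1,
            "abs_A_2": comp.abs_A_2, "abs_CD_2": comp.abs_CD_2, "abs_E_2": comp.abs_E_2,
            "std_A_1": comp.std_A_1, "std_CD_1": comp.std_CD_1, "std_E_1": comp.std_E_1,
            "std_A_2": comp.std_A_2, "std_CD_2": comp.std_CD_2, "std_E_2": comp.std_E_2,
            "broad_h2_1": comp.broad_h2_1, "broad_h2_2": comp.broad_h2_2,
            "rA": corr.rA, "rCD": corr.rCD, "rE": corr.rE,
            "zA": corr.zA, "zCD": corr.zCD, "zE": corr.zE,
            "chi2_full_vs_E": tests.chi2_full_vs_E, "p_full_vs_E": tests.p_full_vs_E,
            "chi2_AE_vs_E": tests.chi2_AE_vs_E, "p_AE_vs_E": tests.p_AE_vs_E,
            "chi2_stability": tests.chi2_stability, "p_stability": tests.p_stability,
            "mean_out_of_range": flag.mean_out_of_range,
            "sd_out_of_range": flag.sd_out_of_range,
            "keep": flag.keep,
        }
        rows.append(row)
    return rows
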