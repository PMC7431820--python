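"""Mixed-model and skew-normal set-comparison tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, skewnorm

from twinmeth.setcompare import (
    SkewNormalRegression,
    compare_sets,
    fit_random_intercept_lmm,
    skew_regress_z,
)


def _long_data(n_sites, var_between, var_within, effect=0.0, member_frac=0.3, seed=0):
    rng = np.random.default_rng(seed)
    member = rng.random(n_sites) < member_frac
    u = rng.normal(0, math.sqrt(var_between), n_sites)
    rows = []
    for s in range(n_sites):
        for t in (1, 2):
            rows.append(
                {
                    "site_id": f"cg{s}",
                    "occasion": t,
                    "member": str(int(member[s])),
                    "value": 0.3 + effect * member[s] + u[s]
                    + rng.normal(0, math.sqrt(var_within)),
                }
            )
    return pd.DataFrame(rows), member


class TestRandomInterceptLmm:
    def test_zero_between_variance_matches_ols(self):
        df, _ = _long_data(400, var_between=0.0, var_within=0.5, effect=0.2, seed=1)
        res = fit_random_intercept_lmm(df, "value", category="member")
        assert res.rho < 0.05
        X = np.column_stack(
            [
                np.ones(len(df)),
                (df["occasion"] == 2).astype(float),
                (df["member"] == "1").astype(float),
            ]
        )
        beta_ols = np.linalg.lstsq(X, df["value"].to_numpy(), rcond=None)[0]
        assert res.fixed_effects["member[1]"] == pytest.approx(beta_ols[2], abs=0.02)

    def test_six_categories_give_wald_df_five(self):
        rng = np.random.default_rng(3)
        islands = ["Island", "North Shore", "South Shore", "North Shelf", "South Shelf", "Open Seas"]
        rows = []
        for s in range(240):
            cat = islands[s % 6]
            for t in (1, 2):
                rows.append(
                    {"site_id": f"cg{s}", "occasion": t, "island": cat,
                     "value": 0.2 + 0.05 * (s % 6) + rng.normal(0, 0.1)}
                )
        res = fit_random_intercept_lmm(pd.DataFrame(rows), "value", category="island")
        assert res.wald_df == 5
        assert res.p < 0.05

    def test_rho_recovery(self):
        df, _ = _long_data(1500, var_between=0.6, var_within=0.4, seed=5)
        res = fit_random_intercept_lmm(df, "value")
        assert res.rho == pytest.approx(0.6, abs=0.05)
        assert res.wald_chi2 is None  # no category -> no Wald test

    def test_single_category_returns_variances_without_wald(self):
        df, _ = _long_data(100, 0.3, 0.3, seed=6)
        df["member"] = "1"
        res = fit_random_intercept_lmm(df, "value", category="member")
        assert res.wald_chi2 is None
        assert res.var_between >= 0 and res.var_within > 0

    def test_needs_at_least_two_sites(self):
        df = pd.DataFrame(
            {"site_id": ["cg1", "cg1"], "occasion": [1, 2], "value": [0.1, 0.2]}
        )
        with pytest.raises(ValueError):
            fit_random_intercept_lmm(df, "value")

    def test_lmm_loglik_at_least_ols_submodel(self):
        df, _ = _long_data(300, var_between=0.4, var_within=0.4, seed=7)
        from twinmeth.setcompare import RandomInterceptModel

        model = RandomInterceptModel().fit(df, "value")
        X = np.column_stack([np.ones(len(df)), (df["occasion"] == 2).astype(float)])
        y = df["value"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sigma2 = float(np.mean(resid**2))
        ll_ols = float(np.sum(norm.logpdf(y, X @ beta, math.sqrt(sigma2))))
        assert model.loglik_ >= ll_ols - 1e-6


class TestCompareSets:
    def test_recovers_heritability_shift(self):
        rows = []
        rng = np.random.default_rng(11)
        member_ids = set()
        for s in range(600):
            member = s < 150
            if member:
                member_ids.add(f"cg{s}")
            u = rng.normal(0, 0.1)
            base = 0.24 + (0.15 if member else 0.0) + u
            rows.append(
                {"site_id": f"cg{s}", "variant": "ADE", "best": True,
                 "broad_h2_1": base + rng.normal(0, 0.05),
                 "broad_h2_2": base - 0.05 + rng.normal(0, 0.05)}
            )
        out = compare_sets(pd.DataFrame(rows), member_ids, components=("broad_h2",))
        assert out.iloc[0]["set_effect"] == pytest.approx(0.15, abs=0.04)
        assert out.iloc[0]["p"] < 1e-6

    def test_null_set_effect_near_zero(self):
        rows = []
        rng = np.random.default_rng(12)
        for s in range(500):
            u = rng.normal(0, 0.1)
            rows.append(
                {"site_id": f"cg{s}", "variant": "ADE", "best": True,
                 "broad_h2_1": 0.25 + u + rng.normal(0, 0.05),
                 "broad_h2_2": 0.20 + u + rng.normal(0, 0.05)}
            )
        random_set = {f"cg{s}" for s in rng.choice(500, 100, replace=False)}
        out = compare_sets(pd.DataFrame(rows), random_set, components=("broad_h2",))
        assert abs(out.iloc[0]["set_effect"]) < 0.05

    def test_set_equal_to_universe_rejected(self):
        df = pd.DataFrame(
            {"site_id": ["cg1", "cg2"], "variant": "ADE", "best": True,
             "broad_h2_1": [0.1, 0.2], "broad_h2_2": [0.1, 0.2]}
        )
        with pytest.raises(ValueError, match="every site"):
            compare_sets(df, {"cg1", "cg2"})

    def test_disjoint_set_rejected(self):
        df = pd.DataFrame(
            {"site_id": ["cg1", "cg2"], "variant": "ADE", "best": True,
             "broad_h2_1": [0.1, 0.2], "broad_h2_2": [0.1, 0.2]}
        )
        with pytest.raises(ValueError, match="intersect"):
            compare_sets(df, {"cgX"})


class TestSkewNormalRegression:
    def test_shape_zero_matches_normal_loglik(self):
        rng = np.random.default_rng(21)
        n = 1500
        g = (rng.random(n) < 0.5).astype(float)
        z = 0.25 + 0.1 * g + rng.normal(0, 0.3, n)
        X = np.column_stack([np.ones(n), g])
        model = SkewNormalRegression(shape_starts=(0.0,)).fit(X, z)
        beta = np.linalg.lstsq(X, z, rcond=None)[0]
        resid = z - X @ beta
        sigma = math.sqrt(np.mean(resid**2))
        ll_norm = float(np.sum(norm.logpdf(z, X @ beta, sigma)))
        assert model.loglik_ == pytest.approx(ll_norm, abs=1e-6)

    def test_group_means_back_transform(self):
        rng = np.random.default_rng(22)
        n = 3000
        g = np.repeat([0, 1], n // 2)
        shape, scale = 4.0, 0.35
        delta = shape / math.sqrt(1 + shape**2)
        noise = skewnorm.rvs(shape, size=n, random_state=rng) * scale
        noise -= scale * delta * math.sqrt(2 / math.pi)  # center to mean zero
        z = np.where(g == 0, np.arctanh(0.24), np.arctanh(0.10)) + noise
        fit = skew_regress_z(z, g)
        assert fit.group_r[0] == pytest.approx(0.24, abs=0.03)
        assert fit.group_r[1] == pytest.approx(0.10, abs=0.03)
        assert fit.shape > 1.0

    def test_identical_z_degenerate(self):
        z = np.full(60, 0.5)
        with pytest.raises(ValueError, match="degenerate|identical"):
            skew_regress_z(z, np.repeat([0, 1], 30))

    def test_small_group_rejected(self):
        z = np.concatenate([np.random.default_rng(0).normal(size=30), [0.1] * 5])
        g = np.array([0] * 30 + [1] * 5)
        with pytest.raises(ValueError, match=">= 10"):
            skew_regress_z(z, g)

    def test_non_finite_z_rejected(self):
        z = np.array([0.1] * 20 + [np.inf] + [0.2] * 19)
        with pytest.raises(ValueError, match="finite"):
            skew_regress_z(z, np.repeat([0, 1], 20))
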