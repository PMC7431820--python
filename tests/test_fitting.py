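"""Model-fitting tests: optimization, nesting, selection, filtering."""

import numpy as np
import pytest

import twinmeth as tm
from twinmeth.fitting import VARIANTS
from twinmeth.records import TwinPairRecord
from twinmeth.simulate import CohortConfig, make_cohort


def test_aic_consistency_enforced(all_fits):
    for fit in all_fits.values():
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_free, abs=1e-9)


def test_nested_variants_never_beat_fuller_ones(all_fits):
    tol = 1e-6
    assert all_fits["AE"].loglik <= all_fits["ACE"].loglik + tol
    assert all_fits["AE"].loglik <= all_fits["ADE"].loglik + tol
    assert all_fits["CE"].loglik <= all_fits["ACE"].loglik + tol
    assert all_fits["E"].loglik <= all_fits["AE"].loglik + tol
    assert all_fits["E"].loglik <= all_fits["CE"].loglik + tol


def test_free_parameter_counts_give_conventional_dfs(all_fits):
    assert all_fits["ADE"].n_free - all_fits["E"].n_free == 6
    assert all_fits["ACE"].n_free - all_fits["E"].n_free == 6
    assert all_fits["AE"].n_free - all_fits["E"].n_free == 3


class TestLrt:
    def test_full_vs_e_df6(self, all_fits):
        chi2, df, p = tm.lrt(all_fits["ADE"], all_fits["E"])
        assert df == 6 and chi2 >= 0 and 0 <= p <= 1

    def test_ae_vs_e_df3(self, all_fits):
        chi2, df, p = tm.lrt(all_fits["AE"], all_fits["E"])
        assert df == 3

    def test_identical_logliks_give_p_one(self, all_fits, fit_factory):
        base = all_fits["ADE"]
        nested = fit_factory(
            base.params, variant="E", loglik=base.loglik,
            n_free=base.n_free - 6, n_pairs=base.n_pairs_used,
        )
        chi2, df, p = tm.lrt(base, nested)
        assert chi2 == 0.0 and p == 1.0

    def test_non_nested_pair_rejected(self, all_fits):
        with pytest.raises(ValueError, match="not nested"):
            tm.lrt(all_fits["ADE"], all_fits["CE"])

    def test_boundary_mixture_reference_is_less_conservative(self, all_fits):
        from twinmeth.fitting import chi_bar_square_sf

        chi2, df, p_naive = tm.lrt(all_fits["ADE"], all_fits["E"])
        _, _, p_mix = tm.lrt(all_fits["ADE"], all_fits["E"], boundary_mixture=True)
        if chi2 > 0:
            assert p_mix <= p_naive
        # with no boundary parameters the mixture reduces to the plain chi2
        from scipy.stats import chi2 as chi2_dist

        assert chi_bar_square_sf(3.0, 0, 3) == pytest.approx(chi2_dist.sf(3.0, 3))


class TestSelectBest:
    def _fit(self, fit_factory, variant, aic, converged=True):
        # choose loglik so that aic comes out as requested with n_free=16
        return fit_factory(
            tm.PathParameters(), variant=variant, loglik=(2 * 16 - aic) / 2,
            n_free=16, converged=converged,
        )

    def test_tie_retains_ade(self, fit_factory):
        ace = self._fit(fit_factory, "ACE", aic=100.0)
        ade = self._fit(fit_factory, "ADE", aic=100.0)
        assert tm.select_best(ace, ade).variant == "ADE"

    def test_lower_aic_wins(self, fit_factory):
        ace = self._fit(fit_factory, "ACE", aic=98.0)
        ade = self._fit(fit_factory, "ADE", aic=100.0)
        assert tm.select_best(ace, ade).variant == "ACE"

    def test_non_converged_fit_loses(self, fit_factory):
        ace = self._fit(fit_factory, "ACE", aic=90.0, converged=False)
        ade = self._fit(fit_factory, "ADE", aic=100.0)
        assert tm.select_best(ace, ade).variant == "ADE"

    def test_neither_converged_flags_site(self, fit_factory):
        ace = self._fit(fit_factory, "ACE", aic=90.0, converged=False)
        ade = self._fit(fit_factory, "ADE", aic=100.0, converged=False)
        assert tm.select_best(ace, ade) is None


class TestFilterSite:
    @staticmethod
    def _records():
        return [
            TwinPairRecord("p1", "MZ", 0, 0, 70.0, 80.0, np.array([1.0, 1.0, 1.0, 1.0])),
            TwinPairRecord("p2", "DZ", 0, 0, 70.0, 80.0, np.array([1.0, 1.0, 1.0, 1.0])),
        ]

    def _fit(self, fit_factory, variant="ACE", **params):
        return fit_factory(tm.PathParameters(**params), variant=variant)

    def test_mean_beyond_bound_under_one_variant_flags(self, fit_factory):
        ace = self._fit(fit_factory, "ACE", beta0_t1=0.0, beta0_t2=6.30, e11=0.5, e22=0.5)
        ade = self._fit(fit_factory, "ADE", beta0_t1=0.0, beta0_t2=0.0, e11=0.5, e22=0.5)
        flag = tm.filter_site(ace, ade, self._records())
        assert flag.mean_out_of_range and not flag.keep

    def test_sd_at_bound_is_not_flagged(self, fit_factory):
        # implied SDs 1.49 and 1.50: "exceeding 1.5" is strict
        ace = self._fit(fit_factory, "ACE", e11=1.49, e22=1.50, e21=0.0)
        ade = self._fit(fit_factory, "ADE", e11=1.49, e22=1.50, e21=0.0)
        flag = tm.filter_site(ace, ade, self._records())
        assert not flag.sd_out_of_range and flag.keep

    def test_sd_above_bound_flags(self, fit_factory):
        ace = self._fit(fit_factory, "ACE", e11=1.51, e22=0.5)
        ade = self._fit(fit_factory, "ADE", e11=0.5, e22=0.5)
        assert tm.filter_site(ace, ade, self._records()).sd_out_of_range

    def test_benign_moments_keep(self, fit_factory):
        ace = self._fit(fit_factory, "ACE", beta0_t1=0.0, beta0_t2=1.0, e11=1.0, e22=1.0)
        ade = self._fit(fit_factory, "ADE", beta0_t1=0.0, beta0_t2=1.0, e11=1.0, e22=1.0)
        assert tm.filter_site(ace, ade, self._records()).keep


class TestRecovery:
    def test_e_only_truth_recovers_occasion_variances(self):
        cohort = make_cohort(
            CohortConfig(n_mz_pairs=250, n_dz_pairs=250, seed=21, id_prefix="R")
        )
        truth = tm.PathParameters(e11=0.4, e21=0.05, e22=0.39, beta0_t1=1.0, beta0_t2=1.1)
        recs = tm.simulate_site(tm.SiteTruth("cg1", truth, "E"), cohort, seed=8)
        fit = tm.fit_variant(recs, "E", tm.FitSettings(seed=2))
        comp = tm.standardize(fit)
        assert comp.total_var_1 == pytest.approx(0.4**2, rel=0.10)
        assert comp.total_var_2 == pytest.approx(0.05**2 + 0.39**2, rel=0.10)

    def test_optimizer_matches_brute_force_on_toy_site(self):
        """Grid maximization over the identified parameters of an occasion-1
        only E model agrees with the optimizer within 1e-4 log-units."""
        mask = np.array([True, False, True, False])
        y1 = np.array([0.8, np.nan, 1.3, np.nan])
        y2 = np.array([1.1, np.nan, 0.6, np.nan])
        recs = [
            TwinPairRecord("p1", "MZ", 0, 0, 74.0, 84.0, y1, mask),
            TwinPairRecord("p2", "DZ", 0, 0, 74.0, 84.0, y2, mask),
        ]
        fit = tm.fit_variant(recs, "E", tm.FitSettings(seed=0))
        # only e11 and beta0_t1 touch the likelihood of these observations
        best_grid = -np.inf
        for e11 in np.linspace(0.05, 1.0, 120):
            for b0 in np.linspace(0.5, 1.5, 120):
                params = tm.PathParameters(e11=e11, e22=1.0, beta0_t1=b0)
                best_grid = max(best_grid, tm.dataset_loglik(params, recs))
        assert fit.loglik >= best_grid - 1e-4


class TestStability:
    def test_constrained_loglik_not_above_unconstrained(self, site_records, all_fits):
        fit = all_fits["ADE"]
        chi2, df, p, constrained = tm.stability_test(
            fit, site_records, tm.FitSettings(seed=4)
        )
        assert df == 3
        assert constrained.loglik <= fit.loglik + 1e-6
        assert chi2 >= 0 and 0 <= p <= 1

    def test_strong_cross_paths_are_detected(self):
        cohort = make_cohort(
            CohortConfig(n_mz_pairs=150, n_dz_pairs=150, seed=31, id_prefix="S")
        )
        truth = tm.params_from_components(
            (0.5, 0.0, 0.5), (0.5, 0.0, 0.5), 0.2, 0.2, (1.0, 0.0, 0.3),
            second_source="D", beta0_t1=1.0, beta0_t2=1.0,
        )
        recs = tm.simulate_site(tm.SiteTruth("cg1", truth, "ADE"), cohort, seed=9)
        st = tm.FitSettings(seed=6)
        fit = tm.fit_variant(recs, "ADE", st)
        chi2, df, p, _ = tm.stability_test(fit, recs, st)
        assert p < 1e-4


class TestRunMethylome:
    def test_all_sites_and_variants_reported(self, tiny_dataset):
        dataset, _ = tiny_dataset
        results, failures = tm.run_methylome(dataset, tm.FitSettings(seed=1))
        assert len(failures) == 0
        assert len(results) == len(dataset) * len(VARIANTS)
        assert results.groupby("site_id")["best"].sum().eq(1).all()

    def test_rerun_is_deterministic(self, tiny_dataset):
        dataset, _ = tiny_dataset
        r1, _ = tm.run_methylome(dataset, tm.FitSettings(seed=1))
        r2, _ = tm.run_methylome(dataset, tm.FitSettings(seed=1))
        from pandas.testing import assert_frame_equal

        assert_frame_equal(r1, r2)

    def test_corrupt_site_recorded_not_fatal(self, tiny_dataset):
        dataset, _ = tiny_dataset
        broken = dict(dataset)
        broken["cg_bad"] = dataset[next(iter(dataset))][:1]  # single pair: unfittable
        results, failures = tm.run_methylome(broken, tm.FitSettings(seed=1))
        assert failures["site_id"].tolist() == ["cg_bad"]
        assert results["site_id"].nunique() == len(dataset)
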