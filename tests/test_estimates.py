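"""Derived-estimate tests: components, correlations, classification, summaries."""

import numpy as np
import pandas as pd
import pytest

import twinmeth as tm
from twinmeth import io
from twinmeth.estimates import classify_low_stability, classify_sites
from twinmeth.records import TwinPairRecord


class TestStandardize:
    def test_equal_squares_split(self, fit_factory):
        fit = fit_factory(
            tm.PathParameters(a11=1.0, s11=1.0, e11=np.sqrt(2.0), second_source="D",
                              a22=1.0, s22=1.0, e22=np.sqrt(2.0))
        )
        comp = tm.standardize(fit)
        assert comp.std_A_1 == pytest.approx(0.25)
        assert comp.std_CD_1 == pytest.approx(0.25)
        assert comp.std_E_1 == pytest.approx(0.50)
        assert comp.broad_h2_1 == pytest.approx(0.50)

    def test_e_only_fit(self, fit_factory):
        comp = tm.standardize(fit_factory(tm.PathParameters(e11=0.7, e22=0.6), variant="E"))
        assert comp.std_E_1 == pytest.approx(1.0)
        assert comp.std_E_2 == pytest.approx(1.0)
        assert comp.broad_h2_1 == pytest.approx(0.0)

    def test_occasion2_accumulates_both_columns(self, fit_factory):
        fit = fit_factory(tm.PathParameters(a11=0.5, a21=0.3, a22=0.4, e11=0.5, e22=0.5))
        comp = tm.standardize(fit)
        assert comp.abs_A_2 == pytest.approx(0.3**2 + 0.4**2)

    def test_ace_broad_heritability_excludes_common_environment(self, fit_factory):
        fit = fit_factory(
            tm.PathParameters(a11=0.5, s11=0.5, e11=0.5, a22=0.5, s22=0.5, e22=0.5,
                              second_source="C"),
            variant="ACE",
        )
        comp = tm.standardize(fit)
        assert comp.broad_h2_1 == pytest.approx(1 / 3)

    def test_components_sum_to_one(self, all_fits):
        for fit in all_fits.values():
            comp = tm.standardize(fit)
            assert comp.std_A_1 + comp.std_CD_1 + comp.std_E_1 == pytest.approx(1.0, abs=1e-9)
            assert comp.abs_A_2 + comp.abs_CD_2 + comp.abs_E_2 == pytest.approx(
                comp.total_var_2, abs=1e-9
            )


class TestCrossTimeCorrelations:
    def test_single_factor_gives_perfect_correlation(self, fit_factory):
        corr = tm.cross_time_correlations(
            fit_factory(tm.PathParameters(a11=0.5, a21=0.4, a22=0.0, e11=1, e22=1))
        )
        assert corr.rA == pytest.approx(1.0)

    def test_zero_cross_path_gives_zero_correlation(self, fit_factory):
        corr = tm.cross_time_correlations(
            fit_factory(tm.PathParameters(a11=0.5, a21=0.0, a22=0.4, e11=1, e22=1))
        )
        assert corr.rA == pytest.approx(0.0)

    def test_zero_variance_source_flagged_undefined(self, fit_factory):
        corr = tm.cross_time_correlations(
            fit_factory(tm.PathParameters(e11=1.0, e21=0.2, e22=0.9), variant="E")
        )
        assert not corr.rA_defined and np.isnan(corr.rA)
        assert corr.rE_defined

    def test_fisher_z_round_trip(self, fit_factory):
        corr = tm.cross_time_correlations(
            fit_factory(tm.PathParameters(a11=0.5, a21=0.3, a22=0.2, e11=1, e22=1))
        )
        assert np.tanh(corr.zA) == pytest.approx(corr.rA, abs=1e-12)

    def test_monte_carlo_oracle_small(self):
        """Path formula equals the empirical correlation of simulated latent
        scores (small-n version of the full oracle check)."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            l11, l21, l22 = rng.uniform(0.2, 1.5), rng.uniform(-1, 1), rng.uniform(0.1, 1.5)
            g = rng.standard_normal((2, 200_000))
            s1 = l11 * g[0]
            s2 = l21 * g[0] + l22 * g[1]
            r_mc = np.corrcoef(s1, s2)[0, 1]
            r_formula = l11 * l21 / np.sqrt(l11**2 * (l21**2 + l22**2))
            assert r_formula == pytest.approx(r_mc, abs=0.01)


class TestClassification:
    @pytest.mark.parametrize(
        "p_stab, e1, e2, expected",
        [
            (0.02, 0.45, 0.80, True),
            (0.005, 0.45, 0.45, False),  # stability significant
            (0.50, 0.95, 0.95, False),  # E-dominated
            (np.nan, 0.40, 0.40, False),  # missing test
        ],
    )
    def test_low_stability_rule(self, p_stab, e1, e2, expected):
        assert classify_low_stability(p_stab, e1, e2) is expected

    def test_classify_round_trips_through_results_file(self, tmp_path, tiny_dataset):
        dataset, _ = tiny_dataset
        results, _ = tm.run_methylome(dataset, tm.FitSettings(seed=1))
        in_memory = classify_sites(results)
        path = tmp_path / "results.tsv"
        io.write_results(results, path)
        re_read = classify_sites(io.read_results(path))
        pd.testing.assert_frame_equal(in_memory, re_read)


class TestEDominance:
    @staticmethod
    def _records_with_values(zygosity_values):
        recs = []
        for i, (zyg, y) in enumerate(zygosity_values):
            recs.append(
                TwinPairRecord(f"p{i}", zyg, 0, 0, 70.0, 80.0, np.asarray(y, dtype=float))
            )
        return recs

    def test_simulated_e_only_site_is_flagged(self):
        from twinmeth.simulate import CohortConfig, make_cohort

        cohort = make_cohort(CohortConfig(n_mz_pairs=250, n_dz_pairs=250, seed=13))
        truth = tm.PathParameters(e11=0.5, e21=0.05, e22=0.5, beta0_t1=1.0, beta0_t2=1.0)
        recs = tm.simulate_site(tm.SiteTruth("cg1", truth, "E"), cohort, seed=3)
        fit = tm.fit_variant(recs, "ADE", tm.FitSettings(seed=7))
        diag = tm.e_dominance_diagnostics(recs, tm.standardize(fit))
        assert diag.e_dominated

    def test_negative_mz_correlation_indicator(self):
        recs = self._records_with_values(
            [
                ("MZ", [1.0, 1.0, -1.0, -0.9]),
                ("MZ", [-1.0, -1.1, 1.0, 1.1]),
                ("MZ", [0.5, 0.4, -0.6, -0.4]),
                ("DZ", [1.0, 1.0, 1.0, 1.1]),
                ("DZ", [-1.0, -1.0, -1.0, -0.9]),
                ("DZ", [0.0, 0.1, 0.0, -0.1]),
            ]
        )
        comp = tm.standardize(
            tm.FitResult("E", tm.PathParameters(e11=1, e22=1), 0.0, 0, 0.0, True, 6)
        )
        diag = tm.e_dominance_diagnostics(recs, comp)
        assert diag.mz_negative is True

    def test_diff_threshold_needs_both_occasions(self):
        # MZ - DZ = -0.05 at both occasions: above the -0.1 threshold
        rng = np.random.default_rng(5)
        recs = []
        for i in range(400):
            zyg = "MZ" if i % 2 == 0 else "DZ"
            rho = 0.20 if zyg == "MZ" else 0.25
            cov = np.array([[1, 0, rho, 0], [0, 1, 0, rho], [rho, 0, 1, 0], [0, rho, 0, 1]])
            y = np.linalg.cholesky(cov) @ rng.standard_normal(4)
            recs.append(TwinPairRecord(f"p{i}", zyg, 0, 0, 70.0, 80.0, y))
        comp = tm.standardize(
            tm.FitResult("E", tm.PathParameters(e11=1, e22=1), 0.0, 0, 0.0, True, 6)
        )
        diag = tm.e_dominance_diagnostics(recs, comp)
        assert diag.diff_negative is False


class TestSummaries:
    def _results(self, std_E=1.0, n=4):
        rows = []
        for i in range(n):
            for variant in ("ADE", "ACE"):
                rows.append(
                    {
                        "site_id": f"cg{i}", "variant": variant, "best": variant == "ADE",
                        "std_A_1": (1 - std_E) / 2, "std_CD_1": (1 - std_E) / 2,
                        "std_E_1": std_E, "std_A_2": 0.0, "std_CD_2": 0.0, "std_E_2": std_E,
                        "abs_A_1": 0.0, "abs_CD_1": 0.0, "abs_E_1": 0.1,
                        "abs_A_2": 0.0, "abs_CD_2": 0.0, "abs_E_2": 0.1,
                        "broad_h2_1": 1 - std_E, "broad_h2_2": 0.0,
                        "sd_1": 0.3 + 0.01 * i, "sd_2": 0.3,
                    }
                )
        return pd.DataFrame(rows)

    def test_degenerate_all_e_summary(self):
        out = tm.summarize_components(self._results(std_E=1.0))
        row = out[out["group"] == "ADE"].iloc[0]
        assert row["std_E_1_mean"] == pytest.approx(1.0)
        assert row["std_E_1_sd"] == pytest.approx(0.0)

    def test_single_site_group_sd_undefined(self):
        out = tm.summarize_components(self._results(n=1))
        assert np.isnan(out[out["group"] == "ADE"].iloc[0]["std_E_1_sd"])

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            tm.summarize_components(pd.DataFrame())


class TestPairedChange:
    def test_identical_vectors(self):
        mean, t, df, ci = tm.paired_change_test([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        assert mean == 0.0 and t == 0.0 and df == 2
        assert ci[0] <= mean <= ci[1]

    def test_recovers_simulated_shift(self):
        rng = np.random.default_rng(1)
        h1 = rng.uniform(0.1, 0.5, 5000)
        h2 = h1 - 0.05 + rng.normal(0, 0.02, 5000)
        mean, t, df, ci = tm.paired_change_test(h1, h2)
        assert mean == pytest.approx(-0.05, abs=0.002)
        assert t < -50 and df == 4999
        assert ci[0] <= mean <= ci[1]


class TestSdH2Correlation:
    def _results(self, rho_sign=1.0, n=200, seed=0):
        rng = np.random.default_rng(seed)
        sd = rng.uniform(0.2, 0.6, n)
        h2 = np.clip(0.5 * rho_sign * (sd - 0.4) + rng.normal(0, 0.05, n) + 0.25, 0, 1)
        return pd.DataFrame(
            {
                "site_id": [f"cg{i}" for i in range(n)],
                "variant": "ADE", "best": True,
                "sd_1": sd, "sd_2": sd,
                "broad_h2_1": h2, "broad_h2_2": h2,
            }
        )

    def test_constructed_positive_relation(self):
        out = tm.sd_h2_correlation(self._results(rho_sign=1.0))
        assert out[1] > 0.5 and out[2] > 0.5

    def test_constant_sd_undefined(self):
        df = self._results()
        df["sd_1"] = 0.3
        assert np.isnan(tm.sd_h2_correlation(df)[1])

    def test_requires_three_sites(self):
        with pytest.raises(ValueError):
            tm.sd_h2_correlation(self._results(n=2))
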