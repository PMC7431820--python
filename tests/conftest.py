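import pytest
from hypothesis import HealthCheck, settings

import twinmeth as tm
from twinmeth.fitting import VARIANTS

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort96():
    """The default two-cohort design: 96 same-sex pairs, 4 singletons."""
    return tm.default_cohorts(seed=0)


@pytest.fixture(scope="session")
def ade_truth():
    """A moderately heritable ADE generating model with cohort scalars."""
    return tm.params_from_components(
        (0.30, 0.20, 0.50),
        (0.25, 0.20, 0.55),
        0.16,
        0.18,
        (0.97, 0.97, 0.20),
        second_source="D",
        k1=0.90,
        k2=0.88,
        beta0_t1=2.0,
        beta0_t2=2.1,
        beta_age=0.01,
        beta_sex=0.05,
        beta_country=-0.05,
    )


@pytest.fixture(scope="session")
def site_records(cohort96, ade_truth):
    truth = tm.SiteTruth("cg_demo", ade_truth, "ADE")
    return tm.simulate_site(truth, cohort96, seed=11)


@pytest.fixture(scope="session")
def all_fits(site_records):
    """All five variant fits on the shared demo site (reused across tests)."""
    fit_settings = tm.FitSettings(seed=5, n_restarts=2)
    return {v: tm.fit_variant(site_records, v, fit_settings) for v in VARIANTS}


@pytest.fixture(scope="session")
def tiny_dataset(cohort96, ade_truth):
    """Three simulated sites on the 96-pair design."""
    sampler = tm.fixed_truth_sampler(ade_truth, "ADE")
    dataset, truth = tm.simulate_methylome(3, sampler, cohort96, master_seed=17)
    return dataset, truth


def make_fit(params, variant="ADE", loglik=0.0, n_free=0, n_pairs=10, converged=True):
    """Hand-built FitResult for tests of pure path arithmetic."""
    return tm.FitResult(
        variant=variant,
        params=params,
        loglik=loglik,
        n_free=n_free,
        aic=-2.0 * loglik + 2 * n_free,
        converged=converged,
        n_pairs_used=n_pairs,
    )


@pytest.fixture(scope="session")
def fit_factory():
    return make_fit
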