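"""Synthetic twin cohorts and per-site methylation data.

Generates data with exactly the statistical structure the analysis assumes:
same-sex MZ/DZ pairs from two cohorts measured twice roughly a decade apart,
per-site M-values drawn from the multivariate normal implied by a bivariate
Cholesky model, cohort-specific SD scalars, and a small number of pairs with
one twin observed at a single occasion.  A truth table accompanies every
simulated methylome so parameter recovery can be checked against the
generating values.

The default cohort configurations emulate the two Scandinavian aging-twin
samples that motivate the design: a Swedish-style cohort (22 MZ + 31 DZ
pairs, 53% female, first measured near 63 years with SD 7.2, re-measured
8.00-11.82 years later, 4 pairs with a single-occasion twin) and a
Danish-style cohort (18 MZ + 25 DZ pairs, 72% female, near 76 years with SD
1.8) whose M-value SDs are scaled by k1 = 0.90 and k2 = 0.88 relative to the
reference cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .kernel import PathParameters, expected_pair_cov, expected_pair_mean
from .records import TwinPairRecord

__all__ = [
    "CohortConfig",
    "SiteTruth",
    "PairSkeleton",
    "SWEDISH_COHORT",
    "DANISH_COHORT",
    "make_cohort",
    "default_cohorts",
    "simulate_site",
    "simulate_methylome",
    "beta_to_m",
    "m_to_beta",
]


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Design parameters of one twin cohort.

    ``country_label`` 0 is the reference cohort; label 1 marks the cohort
    whose SDs the model scales by k1/k2.  Occasion-1 ages are drawn
    Normal(age_t1_mean, age_sd); between-occasion gaps are Uniform over
    ``gap_range`` (``age_gap_mean`` is used only when ``gap_range`` is None).
    ``n_singleton_pairs`` pairs have one twin masked at one occasion.
    """

    n_mz_pairs: int
    n_dz_pairs: int
    country_label: int = 0
    age_t1_mean: float = 63.0
    age_gap_mean: float = 9.9
    age_sd: float = 7.0
    gap_range: Optional[tuple[float, float]] = (8.00, 11.82)
    prop_female: float = 0.5
    n_singleton_pairs: int = 0
    seed: int = 0
    id_prefix: str = "P"

    def __post_init__(self) -> None:
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0 or self.n_singleton_pairs < 0:
            raise ConfigurationError("pair counts must be non-negative")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigurationError("prop_female must lie in [0, 1]")
        if self.country_label not in (0, 1):
            raise ConfigurationError("country_label must be 0 or 1")
        if self.gap_range is not None and self.gap_range[0] > self.gap_range[1]:
            raise ConfigurationError("gap_range min must not exceed max")
        if self.n_singleton_pairs > self.n_mz_pairs + self.n_dz_pairs:
            raise ConfigurationError("n_singleton_pairs exceeds the number of pairs")


#: Cohort emulating the Swedish sample (reference country 0).
SWEDISH_COHORT = CohortConfig(
    n_mz_pairs=22,
    n_dz_pairs=31,
    country_label=0,
    age_t1_mean=62.9,
    age_gap_mean=9.6,
    age_sd=7.2,
    gap_range=(8.00, 11.82),
    prop_female=0.53,
    n_singleton_pairs=4,
    id_prefix="SWE",
)

#: Cohort emulating the Danish sample (scaled country 1).
DANISH_COHORT = CohortConfig(
    n_mz_pairs=18,
    n_dz_pairs=25,
    country_label=1,
    age_t1_mean=76.2,
    age_gap_mean=9.9,
    age_sd=1.8,
    gap_range=(8.00, 11.82),
    prop_female=0.72,
    n_singleton_pairs=0,
    id_prefix="DAN",
)


@dataclass(frozen=True)
class PairSkeleton:
    """A pair's design information before any methylation is simulated."""

    pair_id: str
    zygosity: str
    country: int
    sex: int
    age_t1: float
    age_t2: float
    mask: tuple[bool, bool, bool, bool]


@dataclass(frozen=True)
class SiteTruth:
    """Generating parameters for one simulated site."""

    site_id: str
    params: PathParameters
    variant: str = "ADE"

    def __post_init__(self) -> None:
        if self.variant not in ("ACE", "ADE", "AE", "CE", "E"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")


def make_cohort(config: CohortConfig) -> list[PairSkeleton]:
    """Draw a cohort of pair skeletons; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_mz_pairs + config.n_dz_pairs
    zygs = ["MZ"] * config.n_mz_pairs + ["DZ"] * config.n_dz_pairs
    sexes = (rng.random(n) < config.prop_female).astype(int)
    ages1 = rng.normal(config.age_t1_mean, config.age_sd, size=n)
    if config.gap_range is not None:
        gaps = rng.uniform(config.gap_range[0], config.gap_range[1], size=n)
    else:
        gaps = np.full(n, config.age_gap_mean)
    singleton_idx = set(
        rng.choice(n, size=config.n_singleton_pairs, replace=False).tolist()
        if config.n_singleton_pairs
        else []
    )
    pairs = []
    for i in range(n):
        mask = [True, True, True, True]
        if i in singleton_idx:
            # one twin partner has data at one occasion only
            twin = int(rng.integers(1, 3))
            occasion = int(rng.integers(1, 3))
            missing_slot = (twin - 1) * 2 + (2 - occasion)  # mask the *other* occasion
            mask[missing_slot] = False
        pairs.append(
            PairSkeleton(
                pair_id=f"{config.id_prefix}{i + 1:04d}",
                zygosity=zygs[i],
                country=config.country_label,
                sex=int(sexes[i]),
                age_t1=float(ages1[i]),
                age_t2=float(ages1[i] + gaps[i]),
                mask=tuple(mask),
            )
        )
    return pairs


def default_cohorts(seed: int = 0) -> list[PairSkeleton]:
    """The combined two-cohort design (96 pairs: 40 MZ + 56 DZ)."""
    a = make_cohort(replace(SWEDISH_COHORT, seed=seed))
    b = make_cohort(replace(DANISH_COHORT, seed=seed + 1))
    return a + b


def simulate_site(
    truth: SiteTruth,
    cohorts: Sequence[PairSkeleton],
    seed: int | np.random.Generator = 0,
    emit: str = "m",
) -> list[TwinPairRecord]:
    """Draw one site's pair records from the model-implied normal.

    ``emit="m"`` (default) returns M-values; ``emit="beta"`` maps them to
    methylated fractions via the inverse logit2 transform (values land in
    (0, 1) when the generating means sit in the usual M-value range).
    """
    if not cohorts:
        raise ConfigurationError("cohort must be nonempty")
    if emit not in ("m", "beta"):
        raise ConfigurationError("emit must be 'm' or 'beta'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # group by (zygosity, country) so each covariance is factorised once
    chols: dict[tuple[str, int], np.ndarray] = {}
    records = []
    for sk in cohorts:
        key = (sk.zygosity, sk.country)
        if key not in chols:
            chols[key] = np.linalg.cholesky(
                expected_pair_cov(truth.params, sk.zygosity, sk.country)
            )
        mu = expected_pair_mean(truth.params, sk.age_t1, sk.age_t2, sk.sex, sk.country)
        y = mu + chols[key] @ rng.standard_normal(4)
        mask = np.array(sk.mask)
        if emit == "beta":
            y = m_to_beta(y)
        y = np.where(mask, y, np.nan)
        records.append(
            TwinPairRecord(
                pair_id=sk.pair_id,
                zygosity=sk.zygosity,
                country=sk.country,
                sex=sk.sex,
                age_t1=sk.age_t1,
                age_t2=sk.age_t2,
                y=y,
                mask=mask,
            )
        )
    return records


TruthSampler = Callable[[np.random.Generator, int], SiteTruth]


def params_from_components(
    shares_t1: Sequence[float],
    shares_t2: Sequence[float],
    total_var_t1: float,
    total_var_t2: float,
    r_sources: Sequence[float],
    second_source: str = "D",
    **mean_kwargs,
) -> PathParameters:
    """Cholesky paths realizing target standardized shares and cross-time
    correlations.

    ``shares_t1``/``shares_t2`` are (A, C-or-D, E) fractions summing to 1;
    ``r_sources`` gives the cross-occasion correlation of each source's
    latent scores.  For a source with occasion variances (V1, V2) and
    correlation r the factor is l11 = sqrt(V1), l21 = r sqrt(V2),
    l22 = sqrt(V2 (1 - r^2)).
    """
    shares_t1 = np.asarray(shares_t1, dtype=float)
    shares_t2 = np.asarray(shares_t2, dtype=float)
    for sh in (shares_t1, shares_t2):
        if sh.shape != (3,) or np.any(sh < 0) or abs(sh.sum() - 1.0) > 1e-8:
            raise ConfigurationError("shares must be three non-negative values summing to 1")
    vals = {}
    for name, s1, s2, r in zip(("a", "s", "e"), shares_t1, shares_t2, r_sources):
        v1 = s1 * total_var_t1
        v2 = s2 * total_var_t2
        l11 = float(np.sqrt(v1))
        l21 = float(r * np.sqrt(v2)) if v1 > 0 else 0.0
        l22 = float(np.sqrt(max(v2 - l21 * l21, 0.0)))
        vals[f"{name}11"], vals[f"{name}21"], vals[f"{name}22"] = l11, l21, l22
    return PathParameters(second_source=second_source, **vals, **mean_kwargs)


def aging_methylome_sampler(
    variant: str = "ADE",
    mean_shares_t1: Sequence[float] = (0.111, 0.127, 0.762),
    mean_shares_t2: Sequence[float] = (0.091, 0.089, 0.820),
    concentration: float = 4.0,
    r_genetic: float = 0.97,
    r_second: float = 0.97,
    r_e: float = 0.20,
    k1: float = 0.90,
    k2: float = 0.88,
) -> TruthSampler:
    """Truth sampler emulating an aging methylome.

    Per-site standardized shares are drawn from Dirichlet distributions whose
    means default to the across-site component means a late-life twin
    methylome exhibits (small, declining heritable share; dominant non-shared
    share), with ``concentration`` controlling across-site spread.  Genetic
    sources correlate strongly across the decade while non-shared factors
    correlate weakly; total M-value SDs are log-normal around ~0.35 and
    occasion means sit in the typical bimodal M-value range.
    """

    def sample(rng: np.random.Generator, index: int) -> SiteTruth:
        sh1 = rng.dirichlet(concentration * np.asarray(mean_shares_t1))
        sh2 = rng.dirichlet(concentration * np.asarray(mean_shares_t2))
        sd1 = float(np.exp(rng.normal(np.log(0.35), 0.35)))
        sd2 = sd1 * float(np.exp(rng.normal(0.03, 0.08)))
        beta0 = float(rng.uniform(-4.5, 4.5))
        params = params_from_components(
            sh1,
            sh2,
            sd1**2,
            sd2**2,
            (r_genetic, r_second, r_e),
            second_source="D" if variant in ("ADE",) else "C",
            k1=k1,
            k2=k2,
            beta0_t1=beta0,
            beta0_t2=beta0 + float(rng.normal(0.0, 0.05)),
            beta_age=float(rng.normal(0.0, 0.005)),
            beta_sex=float(rng.normal(0.0, 0.05)),
            beta_country=float(rng.normal(0.0, 0.05)),
        )
        return SiteTruth(site_id=f"cg{index + 1:08d}", params=params, variant=variant)

    return sample


def fixed_truth_sampler(params: PathParameters, variant: str = "ADE") -> TruthSampler:
    """Truth sampler that repeats one generating parameter set at every site."""

    def sample(rng: np.random.Generator, index: int) -> SiteTruth:
        return SiteTruth(site_id=f"cg{index + 1:08d}", params=params, variant=variant)

    return sample


def simulate_methylome(
    n_sites: int,
    truth_sampler: TruthSampler,
    cohorts: Sequence[PairSkeleton],
    master_seed: int = 0,
) -> tuple[dict[str, list[TwinPairRecord]], pd.DataFrame]:
    """Simulate ``n_sites`` independent sites plus their truth table.

    Per-site seeds are spawned reproducibly from ``master_seed`` so individual
    sites can be re-simulated in isolation (or in parallel) bit-identically.
    """
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    dataset: dict[str, list[TwinPairRecord]] = {}
    truth_rows = []
    truth_rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    for i in range(n_sites):
        truth = truth_sampler(truth_rng, i)
        site_rng = np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=(i,))
        )
        dataset[truth.site_id] = simulate_site(truth, cohorts, site_rng)
        p = truth.params
        truth_rows.append(
            {
                "site_id": truth.site_id,
                "variant": truth.variant,
                "a11": p.a11, "a21": p.a21, "a22": p.a22,
                "s11": p.s11, "s21": p.s21, "s22": p.s22,
                "e11": p.e11, "e21": p.e21, "e22": p.e22,
                "second_source": p.second_source,
                "k1": p.k1, "k2": p.k2,
                "beta0_t1": p.beta0_t1, "beta0_t2": p.beta0_t2,
                "beta_age": p.beta_age, "beta_sex": p.beta_sex,
                "beta_country": p.beta_country,
            }
        )
    return dataset, pd.DataFrame(truth_rows)


def beta_to_m(beta, clip: bool = False):
    """M-value from a methylated fraction: M = log2(beta / (1 - beta)).

    Beta values of exactly 0 or 1 have no finite M-value; with ``clip=True``
    inputs are first clipped to [1e-6, 1 - 1e-6], otherwise a domain error is
    raised.
    """
    beta = np.asarray(beta, dtype=float)
    if clip:
        beta = np.clip(beta, 1e-6, 1.0 - 1e-6)
    elif np.any((beta <= 0.0) | (beta >= 1.0)):
        raise ValueError("beta values must lie strictly inside (0, 1); pass clip=True")
    out = np.log2(beta / (1.0 - beta))
    return float(out) if out.ndim == 0 else out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    return float(out) if out.ndim == 0 else out
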