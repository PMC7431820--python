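"""Probability core of the bivariate Cholesky twin model.

The phenotype is a twin pair's M-values at two occasions, stacked as
``(twin1_t1, twin1_t2, twin2_t1, twin2_t2)``.  Three latent sources
contribute: additive genetics (A), a second familial source (either common
environment C or genetic dominance D — not simultaneously identifiable in a
twins-only design) and non-shared factors (E).  Each source has a 2x2
lower-triangular Cholesky factor across the two occasions, so its
within-person covariance contribution is L L' and is positive semidefinite by
construction.

Cross-twin sharing coefficients follow quantitative-genetic expectations: MZ
pairs share A and D fully, DZ pairs share 50% of A and 25% of D; C is shared
fully by both zygosities and E is never shared.  A second cohort ("country 1")
may differ from the reference cohort by free per-occasion SD scalars k1, k2,
applied by pre/post-multiplying the 4x4 covariance with diag(k1, k2, k1, k2).

Means are linear in covariates: per-occasion intercepts plus age (centered at
74 years), sex (0/1) and country (0/1) effects; the age/sex/country slopes are
shared across occasions by default, with an occasion-specific option.

Likelihood is full-information maximum likelihood (FIML): every pair
contributes the multivariate-normal log-density of exactly its observed
slots, so pairs with a twin measured at only one occasion are retained
without imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
from scipy.linalg import solve_triangular

from .records import TwinPairRecord

__all__ = [
    "AGE_CENTER",
    "PathParameters",
    "PairMoments",
    "component_cov",
    "expected_pair_mean",
    "expected_pair_cov",
    "pair_loglik",
    "dataset_loglik",
    "SingularPairCovariance",
]

#: Centering constant for the age covariate (years): the average age across
#: the two occasions in the pooled design the model targets.
AGE_CENTER = 74.0

_LOG_2PI = float(np.log(2.0 * np.pi))


class SingularPairCovariance(np.linalg.LinAlgError):
    """Observed-submatrix covariance is singular for a pair."""

    def __init__(self, pair_id: str):
        super().__init__(f"singular observed-slot covariance for pair {pair_id}")
        self.pair_id = pair_id


@dataclass
class PathParameters:
    """Cholesky paths, mean coefficients and cohort scalars for one model.

    ``second_source`` selects whether the s-paths denote common environment
    (``"C"``) or dominance (``"D"``); diagonal paths carry a >= 0 sign
    convention (the likelihood is invariant to their sign).  ``k1``/``k2``
    scale country-1 standard deviations per occasion, country 0 is the
    reference (scalars fixed at 1 there).

    Mean coefficients ``beta_age``, ``beta_sex`` and ``beta_country`` apply to
    both occasions; setting any of the optional ``*_t2`` coefficients switches
    that covariate to occasion-specific slopes (the ``*_t2`` value is used for
    occasion 2).
    """

    a11: float = 0.0
    a21: float = 0.0
    a22: float = 0.0
    s11: float = 0.0
    s21: float = 0.0
    s22: float = 0.0
    e11: float = 1.0
    e21: float = 0.0
    e22: float = 1.0
    second_source: str = "C"
    k1: float = 1.0
    k2: float = 1.0
    beta0_t1: float = 0.0
    beta0_t2: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_country: float = 0.0
    beta_age_t2: Optional[float] = None
    beta_sex_t2: Optional[float] = None
    beta_country_t2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.second_source not in ("C", "D"):
            raise ValueError("second_source must be 'C' or 'D'")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")

    def replace(self, **kw) -> "PathParameters":
        return replace(self, **kw)

    def occasion_mean(self, occasion: int, age: float, sex: int, country: int) -> float:
        """Model-implied mean of one slot given its covariates."""
        if occasion == 1:
            b0, b_age, b_sex, b_cty = (
                self.beta0_t1,
                self.beta_age,
                self.beta_sex,
                self.beta_country,
            )
        else:
            b0 = self.beta0_t2
            b_age = self.beta_age if self.beta_age_t2 is None else self.beta_age_t2
            b_sex = self.beta_sex if self.beta_sex_t2 is None else self.beta_sex_t2
            b_cty = (
                self.beta_country
                if self.beta_country_t2 is None
                else self.beta_country_t2
            )
        return b0 + b_age * (age - AGE_CENTER) + b_sex * sex + b_cty * country


@dataclass
class PairMoments:
    """Mean vector and covariance of the 4-slot pair phenotype."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != (4,) or self.sigma.shape != (4, 4):
            raise ValueError("PairMoments requires mu (4,) and sigma (4, 4)")


def component_cov(l11: float, l21: float, l22: float) -> np.ndarray:
    """Within-person 2x2 covariance contribution of one source, L @ L.T.

    L is the lower-triangular factor [[l11, 0], [l21, l22]], so the result is
    [[l11^2, l11*l21], [l11*l21, l21^2 + l22^2]] and always PSD.
    """
    return np.array(
        [
            [l11 * l11, l11 * l21],
            [l11 * l21, l21 * l21 + l22 * l22],
        ]
    )


def _cross_coefficients(second_source: str, zygosity: str) -> tuple[float, float]:
    alpha_a = 1.0 if zygosity == "MZ" else 0.5
    if second_source == "C":
        alpha_s = 1.0
    else:  # dominance
        alpha_s = 1.0 if zygosity == "MZ" else 0.25
    return alpha_a, alpha_s


def build_pair_cov(
    a: tuple[float, float, float],
    s: tuple[float, float, float],
    e: tuple[float, float, float],
    second_source: str,
    zygosity: str,
    country: int,
    k1: float = 1.0,
    k2: float = 1.0,
) -> np.ndarray:
    """4x4 pair covariance from raw path triples (fast path used by fitting)."""
    A = component_cov(*a)
    S = component_cov(*s)
    E = component_cov(*e)
    alpha_a, alpha_s = _cross_coefficients(second_source, zygosity)
    within = A + S + E
    cross = alpha_a * A + alpha_s * S
    sigma = np.empty((4, 4))
    sigma[:2, :2] = within
    sigma[2:, 2:] = within
    sigma[:2, 2:] = cross
    sigma[2:, :2] = cross
    if country == 1:
        scale = np.array([k1, k2, k1, k2])
        sigma = sigma * np.outer(scale, scale)
    return sigma


def expected_pair_cov(params: PathParameters, zygosity: str, country: int) -> np.ndarray:
    """Model-implied 4x4 covariance for a pair of given zygosity and country."""
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"zygosity must be MZ or DZ, got {zygosity!r}")
    return build_pair_cov(
        (params.a11, params.a21, params.a22),
        (params.s11, params.s21, params.s22),
        (params.e11, params.e21, params.e22),
        params.second_source,
        zygosity,
        country,
        params.k1,
        params.k2,
    )


def expected_pair_mean(
    params: PathParameters,
    age_t1: float,
    age_t2: float,
    sex: int,
    country: int,
) -> np.ndarray:
    """Length-4 mean vector in slot order (twins share ages, sex, country)."""
    m1 = params.occasion_mean(1, age_t1, sex, country)
    m2 = params.occasion_mean(2, age_t2, sex, country)
    return np.array([m1, m2, m1, m2])


def pair_moments(params: PathParameters, record: TwinPairRecord) -> PairMoments:
    return PairMoments(
        expected_pair_mean(
            params, record.age_t1, record.age_t2, record.sex, record.country
        ),
        expected_pair_cov(params, record.zygosity, record.country),
    )


def pair_loglik(params: PathParameters, record: TwinPairRecord) -> float:
    """FIML contribution of one pair: Gaussian log-density of observed slots."""
    mom = pair_moments(params, record)
    idx = np.flatnonzero(record.mask)
    mu = mom.mu[idx]
    sigma = mom.sigma[np.ix_(idx, idx)]
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise SingularPairCovariance(record.pair_id) from exc
    resid = record.y[idx] - mu
    z = solve_triangular(chol, resid, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return -0.5 * (len(idx) * _LOG_2PI + logdet + float(z @ z))


def dataset_loglik(params: PathParameters, records: Iterable[TwinPairRecord]) -> float:
    """Sum of independent pair contributions over a site's records."""
    records = list(records)
    if not records:
        raise ValueError("dataset_loglik requires at least one pair record")
    return float(sum(pair_loglik(params, r) for r in records))
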