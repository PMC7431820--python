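"""Derived quantities from fitted Cholesky paths.

Turns path estimates into the quantities a twin analysis reports:
standardized and absolute variance components per occasion, broad-sense
heritability (A + D under ADE, A alone under ACE), cross-time etiologic
correlations with Fisher-Z transforms, site classifications (low stability,
E-dominated, significance tiers), and across-site summaries.

All components are reported on the reference-cohort (country 0) scale; the
cohort SD scalars cancel in standardized shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult
from .records import TwinPairRecord

__all__ = [
    "VarianceComponents",
    "CrossTimeCorrelations",
    "SiteClassification",
    "EDominanceDiagnostics",
    "standardize",
    "cross_time_correlations",
    "classify_low_stability",
    "e_dominance_diagnostics",
    "classify_sites",
    "summarize_components",
    "paired_change_test",
    "sd_h2_correlation",
]

#: Fisher-Z clipping bound for |r| (clipped sites are flagged).
R_CLIP = 1.0 - 1e-6

#: Classification thresholds.
P_EPIGENOME = 1e-7
P_NOMINAL_STRICT = 1e-2
P_STABILITY = 0.01
E_DOMINANCE = 0.99
E_LOW_SHARE = 0.5


@dataclass
class VarianceComponents:
    """Absolute (M-value^2, country-0 scale) and standardized components."""

    abs_A_1: float
    abs_CD_1: float
    abs_E_1: float
    abs_A_2: float
    abs_CD_2: float
    abs_E_2: float
    second_source: str
    defined: bool = True

    @property
    def total_var_1(self) -> float:
        return self.abs_A_1 + self.abs_CD_1 + self.abs_E_1

    @property
    def total_var_2(self) -> float:
        return self.abs_A_2 + self.abs_CD_2 + self.abs_E_2

    def _std(self, a: float, total: float) -> float:
        return a / total if total > 0 else np.nan

    @property
    def std_A_1(self) -> float:
        return self._std(self.abs_A_1, self.total_var_1)

    @property
    def std_CD_1(self) -> float:
        return self._std(self.abs_CD_1, self.total_var_1)

    @property
    def std_E_1(self) -> float:
        return self._std(self.abs_E_1, self.total_var_1)

    @property
    def std_A_2(self) -> float:
        return self._std(self.abs_A_2, self.total_var_2)

    @property
    def std_CD_2(self) -> float:
        return self._std(self.abs_CD_2, self.total_var_2)

    @property
    def std_E_2(self) -> float:
        return self._std(self.abs_E_2, self.total_var_2)

    @property
    def broad_h2_1(self) -> float:
        """A + D share under ADE; A alone under ACE (C is not heritable)."""
        if self.second_source == "D":
            return self.std_A_1 + self.std_CD_1
        return self.std_A_1

    @property
    def broad_h2_2(self) -> float:
        if self.second_source == "D":
            return self.std_A_2 + self.std_CD_2
        return self.std_A_2


@dataclass
class CrossTimeCorrelations:
    """Cross-occasion correlations of latent source scores, with Fisher-Z."""

    rA: float
    rCD: float
    rE: float
    rA_defined: bool
    rCD_defined: bool
    rE_defined: bool
    clipped: bool = False

    @property
    def zA(self) -> float:
        return _fisher_z(self.rA) if self.rA_defined else np.nan

    @property
    def zCD(self) -> float:
        return _fisher_z(self.rCD) if self.rCD_defined else np.nan

    @property
    def zE(self) -> float:
        return _fisher_z(self.rE) if self.rE_defined else np.nan


@dataclass
class SiteClassification:
    low_stability: bool
    e_dominated: bool
    significant_1e7: bool
    significant_1e2: bool


@dataclass
class EDominanceDiagnostics:
    """E-dominance flag plus empirical twin-correlation diagnostics."""

    e_dominated: bool
    r_mz: tuple  # per occasion, NaN if too few pairs
    r_dz: tuple
    mz_negative: Optional[bool]  # any MZ correlation < 0
    dz_negative: Optional[bool]  # any DZ correlation < -0.05
    diff_negative: Optional[bool]  # MZ - DZ < -0.1 at each occasion


def _fisher_z(r: float) -> float:
    return float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))


def standardize(fit: FitResult) -> VarianceComponents:
    """Variance components from Cholesky paths, reference-cohort scale.

    Occasion 1 loads only the first column of each factor (abs = l11^2);
    occasion 2 accumulates both (abs = l21^2 + l22^2).  Standardized shares
    divide by the occasion total, so the cohort scalars k1/k2 cancel.
    """
    p = fit.params
    comp = VarianceComponents(
        abs_A_1=p.a11**2,
        abs_CD_1=p.s11**2,
        abs_E_1=p.e11**2,
        abs_A_2=p.a21**2 + p.a22**2,
        abs_CD_2=p.s21**2 + p.s22**2,
        abs_E_2=p.e21**2 + p.e22**2,
        second_source=p.second_source,
    )
    if comp.total_var_1 <= 0 or comp.total_var_2 <= 0:
        comp.defined = False
    return comp


def _path_correlation(l11: float, l21: float, l22: float) -> tuple[float, bool]:
    denom_sq = l11 * l11 * (l21 * l21 + l22 * l22)
    if denom_sq <= 0:
        return np.nan, False
    return float(l11 * l21 / math.sqrt(denom_sq)), True


def cross_time_correlations(fit: FitResult) -> CrossTimeCorrelations:
    """rA, rC-or-rD and rE from the Cholesky paths.

    For one source with factor [[l11, 0], [l21, l22]], the latent scores at
    the two occasions are (l11 z1, l21 z1 + l22 z2), hence
    r = l11 l21 / sqrt(l11^2 (l21^2 + l22^2)).  A source with zero variance at
    either occasion has an undefined correlation and is flagged.
    """
    p = fit.params
    rA, okA = _path_correlation(p.a11, p.a21, p.a22)
    rS, okS = _path_correlation(p.s11, p.s21, p.s22)
    rE, okE = _path_correlation(p.e11, p.e21, p.e22)
    clipped = any(ok and abs(r) > R_CLIP for r, ok in ((rA, okA), (rS, okS), (rE, okE)))
    return CrossTimeCorrelations(rA, rS, rE, okA, okS, okE, clipped)


def classify_low_stability(
    p_stability: float, std_E_1: float, std_E_2: float
) -> bool:
    """Low stability with meaningful familial contributions.

    True when the cross-time association is non-significant (p > .01, df = 3)
    *and* non-shared factors account for < 50% of total variance at one or
    both occasions.
    """
    if not np.isfinite(p_stability):
        return False
    return bool(
        p_stability > P_STABILITY and (std_E_1 < E_LOW_SHARE or std_E_2 < E_LOW_SHARE)
    )


def _twin_correlation(records: Sequence[TwinPairRecord], zygosity: str, occasion: int) -> float:
    slots = (0, 2) if occasion == 1 else (1, 3)
    x, y = [], []
    for rec in records:
        if rec.zygosity == zygosity and rec.mask[slots[0]] and rec.mask[slots[1]]:
            x.append(rec.y[slots[0]])
            y.append(rec.y[slots[1]])
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def e_dominance_diagnostics(
    records: Sequence[TwinPairRecord], components: VarianceComponents
) -> EDominanceDiagnostics:
    """Flag sites where E explains > 99% of variance at both occasions.

    Also reports the empirical MZ/DZ twin correlations (pairwise-complete)
    and three diagnostic indicators such sites typically satisfy: a negative
    MZ correlation, a DZ correlation below -0.05, or MZ - DZ differences
    below -0.1 at each occasion.
    """
    flag = bool(components.std_E_1 > E_DOMINANCE and components.std_E_2 > E_DOMINANCE)
    r_mz = tuple(_twin_correlation(records, "MZ", t) for t in (1, 2))
    r_dz = tuple(_twin_correlation(records, "DZ", t) for t in (1, 2))
    if any(np.isnan(r) for r in (*r_mz, *r_dz)):
        return EDominanceDiagnostics(flag, r_mz, r_dz, None, None, None)
    mz_neg = bool(any(r < 0.0 for r in r_mz))
    dz_neg = bool(any(r < -0.05 for r in r_dz))
    diff_neg = bool(all(m - d < -0.1 for m, d in zip(r_mz, r_dz)))
    return EDominanceDiagnostics(flag, r_mz, r_dz, mz_neg, dz_neg, diff_neg)


def classify_sites(results: pd.DataFrame, best_only: bool = True) -> pd.DataFrame:
    """Per-site classification flags from a results table.

    Operates on the best-variant rows by default (``best_only=False`` uses
    every variant row).  Reproducible from a written results table: applying
    this to ``read_results(write_results(x))`` equals in-memory output.
    """
    rows = results[results["best"]] if best_only else results
    out = rows[["site_id", "variant"]].copy().reset_index(drop=True)
    out["significant_1e7"] = (rows["p_full_vs_E"] < P_EPIGENOME).to_numpy()
    out["significant_1e2"] = (rows["p_full_vs_E"] < P_NOMINAL_STRICT).to_numpy()
    out["e_dominated"] = (
        (rows["std_E_1"] > E_DOMINANCE) & (rows["std_E_2"] > E_DOMINANCE)
    ).to_numpy()
    out["low_stability"] = [
        classify_low_stability(p, e1, e2)
        for p, e1, e2 in zip(rows["p_stability"], rows["std_E_1"], rows["std_E_2"])
    ]
    out["keep"] = rows["keep"].to_numpy()
    return out


_COMPONENT_COLUMNS = [
    "std_A_1", "std_CD_1", "std_E_1", "std_A_2", "std_CD_2", "std_E_2",
    "abs_A_1", "abs_CD_1", "abs_E_1", "abs_A_2", "abs_CD_2", "abs_E_2",
    "broad_h2_1", "broad_h2_2",
]


def summarize_components(results: pd.DataFrame) -> pd.DataFrame:
    """Across-site mean/SD of each component, per variant set.

    Groups mirror the conventional reporting layout: all sites under ADE, the
    ADE-best subset, all sites under ACE, the ACE-best subset.
    """
    if results.empty:
        raise ValueError("summarize_components requires a nonempty results table")
    groups = {
        "ADE": results[results["variant"] == "ADE"],
        "ADE best": results[(results["variant"] == "ADE") & results["best"]],
        "ACE": results[results["variant"] == "ACE"],
        "ACE best": results[(results["variant"] == "ACE") & results["best"]],
    }
    rows = []
    for label, df in groups.items():
        if df.empty:
            continue
        row: dict = {"group": label, "n_sites": len(df)}
        for col in _COMPONENT_COLUMNS:
            vals = df[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"{col}_mean"] = float(np.mean(vals)) if vals.size else np.nan
            row[f"{col}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def paired_change_test(h2_t1: np.ndarray, h2_t2: np.ndarray):
    """Within-site paired t test of the occasion-2 minus occasion-1 change.

    Returns (mean difference, t statistic, df, (ci_low, ci_high)) with the
    classical df = n_sites - 1 and a normal-theory 95% CI.
    """
    h2_t1 = np.asarray(h2_t1, dtype=float)
    h2_t2 = np.asarray(h2_t2, dtype=float)
    if h2_t1.shape != h2_t2.shape or h2_t1.size < 2:
        raise ValueError("paired_change_test requires two equal-length vectors, n >= 2")
    diff = h2_t2 - h2_t1
    n = diff.size
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    se = sd / math.sqrt(n)
    t = mean / se if se > 0 else 0.0
    df = n - 1
    half = stats.t.ppf(0.975, df) * se
    return mean, float(t), df, (mean - half, mean + half)


def sd_h2_correlation(results: pd.DataFrame, variant: str = "ADE") -> dict[int, float]:
    """Pearson r between implied occasion SD and the heritable share.

    Computed per occasion over the best-fitting subset of the requested
    variant; returns NaN (flagged undefined) when either vector is constant.
    """
    df = results[(results["variant"] == variant) & results["best"]]
    if len(df) < 3:
        raise ValueError("sd_h2_correlation requires >= 3 sites")
    out = {}
    for t in (1, 2):
        sd = df[f"sd_{t}"].to_numpy(dtype=float)
        h2 = df[f"broad_h2_{t}"].to_numpy(dtype=float)
        ok = np.isfinite(sd) & np.isfinite(h2)
        sd, h2 = sd[ok], h2[ok]
        if sd.size < 3 or np.std(sd) == 0 or np.std(h2) == 0:
            out[t] = np.nan
        else:
            out[t] = float(stats.pearsonr(sd, h2).statistic)
    return out
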