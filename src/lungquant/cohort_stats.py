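"""Cohort-level statistics for cross-sectional imaging/histology studies.

The analysis plan mirrors the validation study this package targets: data
are screened for normality with Shapiro-Wilk; because such outcome measures
are typically non-normal, analyses run on rank-transformed values. Overall
genotype and age effects use a two-way ANOVA with interaction and Tukey HSD
post-hoc comparisons; when only the genotype main effect is present,
within-timepoint two-sample t-tests on ranks are Bonferroni-corrected
(alpha / number of timepoints, 0.05/4 = 0.0125 for the default design).
Associations between micro-CT and histology outcomes use Spearman rank
correlation on the raw, untransformed values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "PairedOutcomes",
    "SpearmanResult",
    "AnovaResult",
    "TimepointTest",
    "NormalityResult",
    "rank_transform",
    "spearman",
    "two_way_anova_ranked",
    "bonferroni_timepoint_tests",
    "shapiro_wilk_gate",
]

GENOTYPES = ("WT", "TNF-Tg")
DEFAULT_AGES = (3.0, 4.0, 5.5, 12.0)


@dataclass
class PairedOutcomes:
    """Complete per-animal (CT value, histology value) pairs for one outcome pair."""

    animal_ids: np.ndarray
    ct_values: np.ndarray
    histo_values: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids)
        self.ct_values = np.asarray(self.ct_values, dtype=float)
        self.histo_values = np.asarray(self.histo_values, dtype=float)
        if not (len(self.animal_ids) == len(self.ct_values) == len(self.histo_values)):
            raise ValueError("paired columns must have equal length")
        ok = np.isfinite(self.ct_values) & np.isfinite(self.histo_values)
        if not ok.all():  # complete pairs only
            self.animal_ids = self.animal_ids[ok]
            self.ct_values = self.ct_values[ok]
            self.histo_values = self.histo_values[ok]

    @property
    def n(self) -> int:
        return len(self.ct_values)


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact", "t-approx" or "undefined"


@dataclass
class AnovaResult:
    table: pd.DataFrame  # effects x (sum_sq, df, F, PR(>F))
    tukey: pd.DataFrame  # pairwise cell comparisons on ranks
    ss_type: int

    def p_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "PR(>F)"])

    def f_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])


@dataclass
class TimepointTest:
    age_months: float
    t_statistic: float
    p_value: float
    corrected_alpha: float
    significant: bool
    computable: bool
    n_per_group: tuple[int, int]


@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool
    rank_transform_recommended: bool


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties sharing the average rank."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty sample")
    if arr.size < 2:
        raise ValueError("rank transformation needs at least 2 values")
    return stats.rankdata(arr, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(
    x: Sequence[float] | PairedOutcomes,
    y: Sequence[float] | None = None,
    exact_max_n: int = 9,
) -> SpearmanResult:
    """Spearman rank correlation with an exact small-sample p-value.

    rho is the Pearson correlation of tie-averaged ranks. The p-value is a
    two-sided exact permutation probability for n <= ``exact_max_n``
    (enumerating all n! orderings of one margin) and the usual Student-t
    approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2 df otherwise.
    A constant margin leaves rho undefined (NaN, method "undefined").
    """
    if isinstance(x, PairedOutcomes):
        xv, yv = x.ct_values, x.histo_values
    else:
        if y is None:
            raise ValueError("y required when x is not a PairedOutcomes")
        xv, yv = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(xv) != len(yv):
        raise ValueError("x and y must have equal length")
    n = len(xv)
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 complete pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return SpearmanResult(float("nan"), float("nan"), n, "undefined")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    rho = _rho_of_ranks(rx, ry)
    if n <= exact_max_n:
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - ry.mean()
        denom = math.sqrt(float(rxc @ rxc)) * math.sqrt(float((ry - ry.mean()) @ (ry - ry.mean())))
        rhos = (pc @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return SpearmanResult(rho, p, n, "exact")
    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0, n, "t-approx")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, float(p), n, "t-approx")


def _validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    required = {"genotype", "age_months", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    cells = table.groupby(["genotype", "age_months"], observed=True).size()
    genotypes = table["genotype"].unique()
    ages = table["age_months"].unique()
    for g in genotypes:
        for a in ages:
            if (g, a) not in cells.index:
                raise ValueError(f"empty design cell: genotype={g!r}, age_months={a}")
    return table


def two_way_anova_ranked(table: pd.DataFrame, ss_type: int = 2) -> AnovaResult:
    """Two-way ANOVA (genotype x age, with interaction) on rank-transformed values.

    Values are ranked over the whole table, a linear model
    ``rank ~ C(genotype) * C(age_months)`` is fitted by OLS, and effects are
    tested with Type II sums of squares by default (Type III via
    ``ss_type=3``, using sum-to-zero contrasts) — the distinction matters
    only for unbalanced cells. Tukey HSD pairwise comparisons run on the
    ranks across all genotype-by-age cells.
    """
    table = _validate_cohort(table)
    if ss_type not in (2, 3):
        raise ValueError("ss_type must be 2 or 3")
    df = table.copy()
    df["rank_value"] = stats.rankdata(df["value"].to_numpy(dtype=float))
    if np.ptp(df["rank_value"].to_numpy()) == 0:
        # constant response: every effect explains nothing (F = 0 by convention)
        effects = ["genotype", "age_months", "genotype:age_months"]
        zero = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": 0.0, "PR(>F)": 1.0}, index=effects
        )
        return AnovaResult(zero, pd.DataFrame(), ss_type)
    contrast = "Sum" if ss_type == 3 else "Treatment"
    formula = (
        f"rank_value ~ C(genotype, {contrast}) * C(age_months, {contrast})"
    )
    model = ols(formula, data=df).fit()
    raw = anova_lm(model, typ=ss_type)
    rename = {}
    for idx in raw.index:
        if "genotype" in idx and ":" not in idx:
            rename[idx] = "genotype"
        elif "age_months" in idx and ":" not in idx:
            rename[idx] = "age_months"
        elif ":" in idx:
            rename[idx] = "genotype:age_months"
    raw = raw.rename(index=rename)
    if "Intercept" in raw.index:
        raw = raw.drop(index="Intercept")
    cells = (
        df["genotype"].astype(str) + "@" + df["age_months"].astype(float).astype(str)
    )
    tukey = pairwise_tukeyhsd(df["rank_value"].to_numpy(), cells.to_numpy())
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return AnovaResult(raw, tukey_df, ss_type)


def bonferroni_timepoint_tests(
    table: pd.DataFrame,
    alpha: float = 0.05,
    k: int = 4,
    welch: bool = False,
    genotypes: tuple[str, str] = GENOTYPES,
) -> list[TimepointTest]:
    """Genotype comparisons within each timepoint, Bonferroni-corrected.

    Within every age group the two genotypes are compared by a two-sample
    t-test on values ranked within that timepoint (pooled variance by
    default, Welch with ``welch=True``); significance requires
    ``p < alpha / k``. Timepoints with fewer than 2 animals in either group
    are flagged not-computable instead of silently dropped.
    """
    if not 0 < alpha < 1 or k < 1:
        raise ValueError("alpha must be in (0, 1) and k >= 1")
    corrected = alpha / k
    results: list[TimepointTest] = []
    for age, sub in table.groupby("age_months", observed=True, sort=True):
        a = sub.loc[sub["genotype"] == genotypes[0], "value"].to_numpy(dtype=float)
        b = sub.loc[sub["genotype"] == genotypes[1], "value"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            results.append(
                TimepointTest(float(age), float("nan"), float("nan"), corrected,
                              False, False, (len(a), len(b)))
            )
            continue
        ranks = stats.rankdata(np.concatenate([a, b]))
        ra, rb = ranks[: len(a)], ranks[len(a):]
        if np.ptp(ranks) == 0:  # identical groups: no evidence of difference
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(ra, rb, equal_var=not welch)
        results.append(
            TimepointTest(float(age), float(t_stat), float(p), corrected,
                          bool(p < corrected), True, (len(a), len(b)))
        )
    return results


def shapiro_wilk_gate(values: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk normality screen gating the rank transformation.

    Returns the W statistic, p-value, and the decision: p < alpha flags the
    sample non-normal, recommending rank transformation before ANOVA.
    """
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000; got n={arr.size}")
    stat, p = stats.shapiro(arr)
    normal = bool(p >= alpha)
    return NormalityResult(float(stat), float(p), normal, not normal)
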