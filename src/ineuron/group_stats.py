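"""Group-comparison statistics for the per-cell metric tables.

The study contrasts ape and human cells per differentiation day with a
Mann-Whitney U test (morphometry) or Welch's unpaired t test
(electrophysiology), screens normality with Shapiro-Wilk, and tests
day x species effects (and batch effects) with a two-way ANOVA. The
Mann-Whitney exact small-sample path (full enumeration of group
assignments, valid with ties) and the significance-star mapping are
implemented here; large-sample approximations delegate to scipy, the
type-II ANOVA to statsmodels.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ComparisonResult",
    "AnovaResult",
    "significance_stars",
    "mann_whitney",
    "welch_t",
    "two_way_anova",
    "shapiro_screen",
    "summarize_groups",
]

EXACT_N_MAX = 8  # exact enumeration for groups up to this size


def significance_stars(p: float) -> str:
    """p<0.05 -> *, p<0.01 -> **, p<0.001 -> ***."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int

    @property
    def significance_stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class AnovaResult:
    """Per-factor F statistics: factor -> (F, df_num, df_den, p)."""

    factors: dict[str, tuple[float, int, int, float]]

    def p(self, factor: str) -> float:
        return self.factors[factor][3]

    def F(self, factor: str) -> float:
        return self.factors[factor][0]


def _u_statistic(pooled_ranks: np.ndarray, idx_a: Sequence[int],
                 n_a: int) -> float:
    return float(pooled_ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 exact_n_max: int = EXACT_N_MAX) -> ComparisonResult:
    """Two-sided Mann-Whitney U.

    Groups of at most ``exact_n_max`` use the exact conditional null
    distribution (enumeration of all C(n_a+n_b, n_a) assignments on the
    pooled midranks, hence valid under ties); larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    if max(n_a, n_b) <= exact_n_max:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
        n = n_a + n_b
        us = np.array([_u_statistic(ranks, combo, n_a)
                       for combo in itertools.combinations(range(n), n_a)])
        p_low = np.mean(us <= u_obs + 1e-12)
        p_high = np.mean(us >= u_obs - 1e-12)
        p = min(1.0, 2.0 * min(p_low, p_high))
        return ComparisonResult("mann_whitney_exact", u_obs, float(p),
                                n_a, n_b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return ComparisonResult("mann_whitney_asymptotic", float(res.statistic),
                            float(res.pvalue), n_a, n_b)


def welch_t(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Welch's unpaired t with Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t needs at least 2 values per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # degenerate: no within-group variance
        if a.mean() == b.mean():
            return ComparisonResult("welch_t", 0.0, 1.0, a.size, b.size)
        return ComparisonResult("welch_t", math.inf, 0.0, a.size, b.size)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult("welch_t", float(res.statistic),
                            float(res.pvalue), a.size, b.size)


def two_way_anova(df: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str, interaction: bool = True,
                  typ: int = 2) -> AnovaResult:
    """Two-factor ANOVA with interaction, type-II sums of squares by
    default (appropriate for the study's unbalanced day x species cells)."""
    for col in (value, factor_a, factor_b):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if df[factor_a].nunique() < 2 or df[factor_b].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    op = "*" if interaction else "+"
    model = smf.ols(f"Q('{value}') ~ C(Q('{factor_a}')) {op} "
                    f"C(Q('{factor_b}'))", data=df).fit()
    table = sm.stats.anova_lm(model, typ=typ)
    resid_df = int(table.loc["Residual", "df"])
    factors: dict[str, tuple[float, int, int, float]] = {}
    rename = {f"C(Q('{factor_a}'))": factor_a,
              f"C(Q('{factor_b}'))": factor_b,
              f"C(Q('{factor_a}')):C(Q('{factor_b}'))": "interaction"}
    for row, label in rename.items():
        if row in table.index:
            F = float(table.loc[row, "F"])
            p = float(table.loc[row, "PR(>F)"])
            if not np.isfinite(F):
                raise ValueError(f"aliased factor {label!r} (F undefined)")
            factors[label] = (F, int(table.loc[row, "df"]), resid_df, p)
    return AnovaResult(factors)


def shapiro_screen(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality screen; defined for 3 <= n <= 5000 and
    non-constant samples."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: W undefined")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def summarize_groups(values_a: Sequence[float], values_b: Sequence[float],
                     label_a: str = "ape", label_b: str = "human"
                     ) -> dict:
    """n/mean/median/SD/SEM per group plus the two headline contrasts."""
    out: dict = {}
    for label, v in ((label_a, np.asarray(values_a, dtype=float)),
                     (label_b, np.asarray(values_b, dtype=float))):
        out[f"n_{label}"] = int(v.size)
        out[f"mean_{label}"] = float(v.mean()) if v.size else math.nan
        out[f"median_{label}"] = float(np.median(v)) if v.size else math.nan
        out[f"sd_{label}"] = float(v.std(ddof=1)) if v.size > 1 else math.nan
        out[f"sem_{label}"] = (float(v.std(ddof=1) / math.sqrt(v.size))
                               if v.size > 1 else math.nan)
        try:
            _, p_sw = shapiro_screen(v)
            out[f"shapiro_p_{label}"] = p_sw
        except ValueError:
            out[f"shapiro_p_{label}"] = math.nan
    if len(values_a) and len(values_b):
        mw = mann_whitney(values_a, values_b)
        out["mw_p"] = mw.p_value
        out["mw_stars"] = mw.significance_stars
        try:
            wt = welch_t(values_a, values_b)
            out["welch_p"] = wt.p_value
            out["welch_stars"] = wt.significance_stars
        except ValueError:
            out["welch_p"] = math.nan
            out["welch_stars"] = ""
    return out
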