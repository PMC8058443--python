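"""Group-comparison layer: mean comparisons with Bonferroni-corrected
post hoc tests and chi-square comparison of per-cell categorical flags.

Results are reported as mean +/- SE per group.  Two groups are compared
with an unpaired t-test; multiple groups with one-way (or two-way) ANOVA
followed by pairwise t-tests with Bonferroni adjustment
(p_adj = min(1, m * p_raw)).  Categorical per-cell flags (has DADs, has
waves, has embers) are compared with a chi-square test on the flag x
group contingency table, without Yates continuity correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MeanComparisonReport", "ProportionReport", "compare_means", "compare_proportions"]

ALPHA = 0.05


@dataclass
class MeanComparisonReport:
    design: str
    summary: pd.DataFrame = field(repr=False)  # mean, se, n per group
    statistic: float = float("nan")
    p_value: float = float("nan")
    pairwise: pd.DataFrame | None = field(default=None, repr=False)
    anova_table: pd.DataFrame | None = field(default=None, repr=False)
    significant: bool = False


@dataclass
class ProportionReport:
    chi2: float
    df: int
    p_value: float
    table: pd.DataFrame = field(repr=False)
    significant: bool = False


def _group_summary(table: pd.DataFrame, value: str, group: str) -> pd.DataFrame:
    g = table.groupby(group)[value]
    out = pd.DataFrame({"mean": g.mean(), "se": g.sem(), "n": g.size()})
    return out


def compare_means(
    table: pd.DataFrame,
    value_column: str,
    group_column: str = "group",
    design: str = "auto",
    factors: tuple[str, str] | None = None,
    alpha: float = ALPHA,
) -> MeanComparisonReport:
    """Compare group means of one measurement column.

    ``design`` is ``two-group`` (unpaired t-test), ``one-way`` (ANOVA with
    Bonferroni-adjusted pairwise t-tests), ``two-way`` (fixed-effects
    ANOVA on the two ``factors``) or ``auto`` (picks two-group/one-way by
    the number of groups).
    """
    if design == "two-way":
        return _two_way(table, value_column, factors, alpha)

    groups = [(name, sub[value_column].to_numpy(float)) for name, sub in table.groupby(group_column)]
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for name, vals in groups:
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    if design == "auto":
        design = "two-group" if len(groups) == 2 else "one-way"

    summary = _group_summary(table, value_column, group_column)
    if design == "two-group":
        if len(groups) != 2:
            raise ValueError("two-group design requires exactly 2 groups")
        t, p = stats.ttest_ind(groups[0][1], groups[1][1])
        return MeanComparisonReport(
            design=design, summary=summary, statistic=float(t), p_value=float(p),
            significant=bool(p < alpha),
        )
    if design != "one-way":
        raise ValueError(f"unknown design {design!r}")

    f, p = stats.f_oneway(*[vals for _, vals in groups])
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for (na, va), (nb, vb) in combinations(groups, 2):
        t, pr = stats.ttest_ind(va, vb)
        rows.append(
            {
                "group_a": na,
                "group_b": nb,
                "t": float(t),
                "p_raw": float(pr),
                "p_bonferroni": min(1.0, m * float(pr)),
            }
        )
    pairwise = pd.DataFrame(rows)
    pairwise["significant"] = pairwise["p_bonferroni"] < alpha
    return MeanComparisonReport(
        design=design, summary=summary, statistic=float(f), p_value=float(p),
        pairwise=pairwise, significant=bool(p < alpha),
    )


def _two_way(table: pd.DataFrame, value: str, factors, alpha: float) -> MeanComparisonReport:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if not factors or len(factors) != 2:
        raise ValueError("two-way design requires factors=(factor_a, factor_b)")
    fa, fb = factors
    data = table.rename(columns={value: "_y"})
    model = ols(f"_y ~ C({fa}) * C({fb})", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    summary = _group_summary(table.assign(_cell=table[fa].astype(str) + ":" + table[fb].astype(str)), value, "_cell")
    p_main = float(anova.loc[f"C({fa})", "PR(>F)"])
    return MeanComparisonReport(
        design="two-way", summary=summary,
        statistic=float(anova.loc[f"C({fa})", "F"]), p_value=p_main,
        anova_table=anova, significant=bool(p_main < alpha),
    )


def compare_proportions(
    table: pd.DataFrame,
    flag_column: str,
    group_column: str = "group",
    continuity_correction: bool = False,
    alpha: float = ALPHA,
) -> ProportionReport:
    """Chi-square test of a boolean per-cell flag across groups."""
    counts = table.groupby(group_column)[flag_column].agg(["sum", "count"])
    if (counts["count"] == 0).any() or counts.shape[0] < 2:
        raise ValueError("every group needs at least one cell")
    contingency = pd.DataFrame(
        {
            "positive": counts["sum"].astype(int),
            "negative": (counts["count"] - counts["sum"]).astype(int),
        }
    )
    chi2, p, df, _ = stats.chi2_contingency(contingency.to_numpy(), correction=continuity_correction)
    return ProportionReport(
        chi2=float(chi2), df=int(df), p_value=float(p), table=contingency,
        significant=bool(p < alpha),
    )
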