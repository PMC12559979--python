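"""Group comparisons in figure-legend style.

Deliberately thin wrappers over scipy/statsmodels so the pipeline can emit
the comparisons the study designs call for: one-way ANOVA with Tukey's HSD
(studentized-range adjustment), balanced two-way ANOVA (type-II sums of
squares), the unpaired two-sided t test (pooled variance by default, Welch
optional), and simple linear regression with a two-sided t test on the
slope.  Data are reported as mean +/- SD per group with alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "LinregResult",
    "group_summary",
    "anova_tukey",
    "two_way_anova",
    "unpaired_t",
    "simple_linreg",
]

ALPHA = 0.05


@dataclass
class GroupSummary:
    """Mean +/- SD and n for one group."""

    group: str
    mean: float
    sd: float
    n: int


@dataclass
class ComparisonResult:
    """Omnibus F/p plus Tukey-adjusted and unadjusted pairwise p values."""

    groups: list[GroupSummary]
    f_statistic: float
    p_value: float
    pairwise_p: dict[tuple[str, str], float]
    pairwise_p_unadjusted: dict[tuple[str, str], float] = field(default_factory=dict)
    alpha: float = ALPHA


@dataclass
class LinregResult:
    slope: float
    intercept: float
    r2: float
    p_value: float


def _split_groups(values, group) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    if values.size != group.size:
        raise ValueError("values and group must have equal length")
    return {str(g): values[group == g] for g in pd.unique(group)}


def group_summary(values, group) -> list[GroupSummary]:
    """Mean +/- SD (ddof=1) and n per group, in order of first appearance."""
    out = []
    for g, v in _split_groups(values, group).items():
        out.append(
            GroupSummary(g, float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0, int(v.size))
        )
    return out


def anova_tukey(values, group) -> ComparisonResult:
    """One-way ANOVA with Tukey's HSD post hoc test.

    Unadjusted pairwise p values use the pooled-MSE t statistic on N-k
    degrees of freedom; Tukey adjustment uses the studentized-range
    distribution (scipy's ``tukey_hsd``).
    """
    groups = _split_groups(values, group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("every group needs at least 2 values")
    names = list(groups)
    arrays = [groups[g] for g in names]
    f_stat, p = sps.f_oneway(*arrays)
    tk = sps.tukey_hsd(*arrays)
    # pooled MSE for unadjusted pairwise t tests
    n_tot = sum(a.size for a in arrays)
    k = len(arrays)
    mse = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / (n_tot - k)
    pairwise, unadj = {}, {}
    for i in range(k):
        for j in range(i + 1, k):
            pairwise[(names[i], names[j])] = float(tk.pvalue[i, j])
            se = np.sqrt(mse * (1 / arrays[i].size + 1 / arrays[j].size))
            t = (arrays[i].mean() - arrays[j].mean()) / se
            unadj[(names[i], names[j])] = float(
                2 * sps.t.sf(abs(t), n_tot - k)
            )
    return ComparisonResult(
        groups=group_summary(values, group),
        f_statistic=float(f_stat),
        p_value=float(p),
        pairwise_p=pairwise,
        pairwise_p_unadjusted=unadj,
    )


def two_way_anova(values, factor_a, factor_b) -> pd.DataFrame:
    """Two-way ANOVA with interaction, type-II sums of squares.

    Returns the statsmodels ANOVA table (rows: both main effects, the
    interaction and the residual) with ``F`` and ``PR(>F)`` columns.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": np.asarray(factor_a).astype(str),
            "b": np.asarray(factor_b).astype(str),
        }
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("both factors need at least 2 levels")
    if (df.groupby(["a", "b"]).size().unstack().isna().any().any()):
        raise ValueError("empty factor cells")
    model = smf.ols("value ~ C(a) * C(b)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def unpaired_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided unpaired t test; pooled variance by default, Welch optional."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def simple_linreg(x, y) -> LinregResult:
    """OLS simple linear regression with a two-sided t test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("slope undefined: x values are constant")
    res = sps.linregress(x, y)
    return LinregResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )
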