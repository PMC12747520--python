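"""Group statistics matching the study's reporting conventions: pooled
Student t-test, one-way and two-way ANOVA, mean +/- SD summaries.

The two-way decomposition uses type-II sums of squares (equal to the
classical decomposition for balanced designs).  Post-hoc pairwise t-tests
with Holm adjustment are provided as an optional extra, clearly an artifact
choice since the omnibus tests are the primary read-out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    flag: str | None = None

    def __iter__(self):
        return iter((self.t, self.df, self.p))


def t_test_2sample(a, b) -> TTestResult:
    """Two-sided pooled-variance Student t-test; df = n_a + n_b - 2.

    Degenerate cases: zero pooled variance with equal means reports t=0,
    p=1 by convention; zero variance with unequal means is flagged (the
    statistic diverges).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return TTestResult(t=t, df=df, p=0.0, flag="zero variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def one_way_anova(groups) -> tuple[float, int, int, float]:
    """Classical between/within F statistic over >= 2 groups.

    Returns (F, df1, df2, p).  All-identical groups give F=0, p=1; a fully
    degenerate table (zero within- and between-group variance) reports the
    same convention.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n = sum(g.size for g in gs)
    k = len(gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def two_way_anova(table: pd.DataFrame, value: str = "value",
                  factor_a: str = "a", factor_b: str = "b",
                  ) -> dict[str, tuple[float, float, float, float]]:
    """Two-way ANOVA with type-II sums of squares.

    ``table`` holds one replicate per row with two categorical factor
    columns.  The interaction term requires >= 2 replicates per cell;
    empty cells are an error.  Returns per-effect (F, df_num, df_den, p).
    """
    for col in (value, factor_a, factor_b):
        if col not in table.columns:
            raise KeyError(f"missing column {col!r}")
    counts = table.groupby([factor_a, factor_b], observed=True)[value].count()
    n_a = table[factor_a].nunique()
    n_b = table[factor_b].nunique()
    if len(counts) < n_a * n_b:
        raise ValueError("empty cells in the two-way design")
    with_interaction = (counts >= 2).all()
    op = "*" if with_interaction else "+"
    model = smf.ols(
        f"Q('{value}') ~ C(Q('{factor_a}')) {op} C(Q('{factor_b}'))",
        data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    out: dict[str, tuple[float, float, float, float]] = {}
    df_resid = float(aov.loc["Residual", "df"])
    for row in aov.index:
        if row == "Residual":
            continue
        name = ("interaction" if ":" in row
                else factor_a if factor_a in row else factor_b)
        out[name] = (float(aov.loc[row, "F"]), float(aov.loc[row, "df"]),
                     df_resid, float(aov.loc[row, "PR(>F)"]))
    return out


def summarize(groups: dict[str, "np.ndarray | list"]) -> pd.DataFrame:
    """Mean +/- sample SD (n-1 denominator) per group, with n.

    Single-value groups report SD as not available (NaN, formatted "NA").
    """
    if not groups:
        raise ValueError("no groups to summarize")
    rows = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
        sd_txt = "NA" if np.isnan(sd) else f"{sd:.4g}"
        rows.append(dict(group=name, mean=mean, sd=sd, n=int(v.size),
                         formatted=f"{mean:.4g} ± {sd_txt} (n={v.size})"))
    return pd.DataFrame(rows).set_index("group")


def pairwise_ttests(groups: dict[str, "np.ndarray | list"],
                    adjust: str = "holm") -> pd.DataFrame:
    """Optional Holm-adjusted pairwise pooled t-tests (post-hoc extra)."""
    names = list(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = t_test_2sample(groups[names[i]], groups[names[j]])
            rows.append(dict(a=names[i], b=names[j], t=r.t, df=r.df, p=r.p))
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"], method=adjust)[1]
    return df
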