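"""Group comparisons: Welch's t, two-way ANOVA with Sidak/Tukey post hocs.

Thin wrappers over scipy/statsmodels returning a uniform record type, so
pipeline outputs carry statistic, df and p side by side regardless of test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, ...]
    statistic_name: str       # welch_t | anova_F | sidak | tukey
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    adjusted: bool = False
    note: str = ""


def welch_t(sample_a, sample_b,
            names: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Unpaired two-sided t-test with Welch's correction.

    Uses the Welch statistic with Welch-Satterthwaite degrees of freedom;
    both samples need n >= 2 and at least one must have positive variance.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # Identical degenerate samples: no evidence of difference.
            return GroupComparison(names, "welch_t", 0.0,
                                   float(a.size + b.size - 2), 1.0,
                                   note="zero variance in both samples")
        raise ValueError("both samples have zero variance but unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(names, "welch_t", float(res.statistic),
                           float(res.df), float(res.pvalue))


def sidak_adjust(p_values) -> np.ndarray:
    """Sidak multiple-comparison adjustment: 1 - (1 - p)^m (monotone, >= raw p)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    return 1.0 - (1.0 - p) ** m


def two_way_anova_posthoc(table: pd.DataFrame,
                          value: str,
                          factor_a: str,
                          factor_b: str,
                          method: str = "sidak") -> dict:
    """Two-way ANOVA (with interaction) plus pairwise post-hoc comparisons.

    ``table`` is a tidy frame with one measurement per row.  Returns a dict
    with ``anova`` (list of GroupComparison: main effects + interaction) and
    ``posthoc`` (list of GroupComparison across levels of ``factor_a``
    within each level of ``factor_b``, adjusted by ``method``:
    ``sidak`` = pairwise Welch t with Sidak correction, ``tukey`` = Tukey's
    HSD).  Degenerate designs (a factor with one level, an empty cell, or
    zero residual variance) raise or flag rather than returning nonsense.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if method not in ("sidak", "tukey"):
        raise ValueError("method must be 'sidak' or 'tukey'")
    df = table[[value, factor_a, factor_b]].dropna().copy()
    levels_a = sorted(df[factor_a].astype(str).unique())
    levels_b = sorted(df[factor_b].astype(str).unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs >= 2 levels")
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index or counts.loc[(la, lb)] == 0:
                raise ValueError(f"empty design cell ({factor_a}={la}, {factor_b}={lb})")

    df = df.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    if model.ssr <= 1e-12 * max(float(model.centered_tss), 1.0):
        return {
            "anova": [GroupComparison(tuple(levels_a), "anova_F", np.nan, None,
                                      np.nan, note="no variance")],
            "posthoc": [],
        }
    aov = sm.stats.anova_lm(model, typ=2)
    label_of = {"C(_a)": factor_a, "C(_b)": factor_b,
                "C(_a):C(_b)": f"{factor_a}:{factor_b}"}
    anova_rows = []
    df_resid = float(aov.loc["Residual", "df"])
    for term, row in aov.iterrows():
        if term == "Residual":
            continue
        anova_rows.append(GroupComparison(
            (label_of.get(term, term),), "anova_F", float(row["F"]),
            (float(row["df"]), df_resid), float(row["PR(>F)"])))

    posthoc: list[GroupComparison] = []
    for lb in levels_b:
        sub = df.loc[df["_b"].astype(str) == lb]
        if method == "tukey":
            res = pairwise_tukeyhsd(sub["_y"], sub["_a"].astype(str))
            summary = res.summary().data[1:]
            for row in summary:
                g1, g2, meandiff, p_adj = row[0], row[1], float(row[2]), float(row[3])
                posthoc.append(GroupComparison(
                    (f"{g1}|{factor_b}={lb}", f"{g2}|{factor_b}={lb}"),
                    "tukey", meandiff, None, p_adj, adjusted=True))
        else:
            pairs, raw = [], []
            for i, g1 in enumerate(levels_a):
                for g2 in levels_a[i + 1:]:
                    cmp = welch_t(sub.loc[sub["_a"].astype(str) == g1, "_y"],
                                  sub.loc[sub["_a"].astype(str) == g2, "_y"],
                                  names=(g1, g2))
                    pairs.append(cmp)
                    raw.append(cmp.p_value)
            adj = sidak_adjust(raw)
            for cmp, p_adj in zip(pairs, adj):
                posthoc.append(GroupComparison(
                    (f"{cmp.groups[0]}|{factor_b}={lb}",
                     f"{cmp.groups[1]}|{factor_b}={lb}"),
                    "sidak", cmp.statistic, cmp.df, float(p_adj), adjusted=True))
    return {"anova": anova_rows, "posthoc": posthoc}
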