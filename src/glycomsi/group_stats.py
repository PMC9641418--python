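"""Group comparisons: one-/two-way ANOVA with Tukey HSD and t-tests.

These are the designs used for the regional figures: one-way ANOVA with
Tukey's multiple comparisons for total glycogen across ROIs, two-way ANOVA
(region x chain length) with Tukey comparisons within each chain length,
and two-tailed t-tests for two-group chain-length comparisons.  Significance
bands follow the figure-caption convention (* 0.01<p<0.05 up to ****).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "one_way_anova_tukey",
    "two_way_anova_tukey",
    "t_test_two_tailed",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Star band for an (adjusted) p-value, per figure-caption convention."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    """Omnibus statistic plus a pairwise table of adjusted comparisons."""

    design: str  # one_way | two_way | t_test
    statistic: float
    p_value: float
    pairwise: pd.DataFrame
    effects: pd.DataFrame | None = None  # two-way main/interaction F table
    flags: list[str] | None = None


def _check_groups(groups: Mapping[str, Sequence[float]], min_groups: int = 2):
    if len(groups) < min_groups:
        raise ValueError(f"need >= {min_groups} groups, got {len(groups)}")
    arrays = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {name!r} contains non-finite values")
        arrays[name] = arr
    return arrays


def one_way_anova_tukey(groups: Mapping[str, Sequence[float]],
                        ) -> ComparisonResult:
    """Classical one-way ANOVA F test with Tukey HSD adjusted pairwise p.

    Tukey adjusted p-values come from the studentized-range distribution
    with the pooled within-group variance.
    """
    arrays = _check_groups(groups)
    names = list(arrays)
    samples = [arrays[n] for n in names]
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("degenerate design: zero within-group variance everywhere")
    f_stat, p = stats.f_oneway(*samples)
    tk = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            adj_p = float(tk.pvalue[i, j])
            rows.append({
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(samples[i].mean() - samples[j].mean()),
                "adj_p": adj_p,
                "stars": significance_stars(adj_p),
            })
    return ComparisonResult(design="one_way", statistic=float(f_stat),
                            p_value=float(p), pairwise=pd.DataFrame(rows))


def two_way_anova_tukey(values: Sequence[float], factor_a: Sequence,
                        factor_b: Sequence) -> ComparisonResult:
    """Two-way ANOVA (A, B, A:B) with Tukey comparisons of A within each B.

    The pairwise comparisons mirror the "Tukey's multiple comparisons for
    each glycogen chain length" design: within every level of factor B
    (chain length), the levels of factor A (region/group) are compared with
    the studentized-range distribution using the pooled residual mean
    square of the full two-way model.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "A": pd.Categorical(factor_a),
        "B": pd.Categorical(factor_b),
    })
    if not np.all(np.isfinite(df["value"])):
        raise ValueError("values contain non-finite entries")
    cell_counts = df.groupby(["A", "B"], observed=False).size().unstack()
    empty = [(a, b) for a in cell_counts.index for b in cell_counts.columns
             if not cell_counts.loc[a, b] or cell_counts.loc[a, b] < 2]
    if empty:
        raise ValueError(f"cells with n < 2: {empty}")
    model = smf.ols("value ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    df_resid = float(table.loc["Residual", "df"])
    a_levels = list(df["A"].cat.categories)
    k = len(a_levels)
    rows = []
    for b in df["B"].cat.categories:
        sub = df[df["B"] == b]
        cells = {a: sub.loc[sub["A"] == a, "value"].to_numpy() for a in a_levels}
        for i in range(k):
            for j in range(i + 1, k):
                xi, xj = cells[a_levels[i]], cells[a_levels[j]]
                diff = xi.mean() - xj.mean()
                se = np.sqrt(mse / 2 * (1 / len(xi) + 1 / len(xj)))
                q = abs(diff) / se
                adj_p = float(stats.studentized_range.sf(q, k, df_resid))
                adj_p = min(max(adj_p, 0.0), 1.0)
                rows.append({
                    "factor_b": b,
                    "group_a": a_levels[i],
                    "group_b": a_levels[j],
                    "mean_diff": float(diff),
                    "adj_p": adj_p,
                    "stars": significance_stars(adj_p),
                })
    interaction = [ix for ix in table.index if ":" in ix][0]
    return ComparisonResult(
        design="two_way",
        statistic=float(table.loc[interaction, "F"]),
        p_value=float(table.loc[interaction, "PR(>F)"]),
        pairwise=pd.DataFrame(rows),
        effects=table,
    )


def t_test_two_tailed(sample_a: Sequence[float], sample_b: Sequence[float],
                      paired: bool = False, pooled: bool = False
                      ) -> ComparisonResult:
    """Two-tailed t-test; Welch by default for unpaired samples.

    Degenerate input (zero variance in both samples, equal means) returns
    p = 1 with a flag rather than NaN.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if paired and a.size != b.size:
        raise ValueError("paired samples must have equal n")
    flags: list[str] = []
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            stat, p = 0.0, 1.0
            flags.append("zero variance in both samples; p = 1 by convention")
        else:
            stat, p = np.inf, 0.0
            flags.append("zero variance in both samples with unequal means")
    elif paired and np.ptp(a - b) == 0:
        # constant difference: zero variance of the paired differences
        if (a - b)[0] == 0:
            stat, p = 0.0, 1.0
            flags.append("identical paired samples; p = 1 by convention")
        else:
            stat, p = np.inf, 0.0
            flags.append("constant nonzero paired difference")
    elif paired:
        stat, p = stats.ttest_rel(a, b)
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=pooled)
    p = float(p)
    pairwise = pd.DataFrame([{
        "group_a": "a", "group_b": "b",
        "mean_diff": float(a.mean() - b.mean()),
        "adj_p": p, "stars": significance_stars(p),
    }])
    return ComparisonResult(design="t_test", statistic=float(stat), p_value=p,
                            pairwise=pairwise, flags=flags or None)
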