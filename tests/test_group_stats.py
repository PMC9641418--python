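"""ANOVA/Tukey and t-test behavior against hand-rolled oracles.

The one-way oracle computes F and Tukey adjusted p from first principles
(sums of squares and the studentized-range distribution) on a small
textbook-style fixture, independent of the implementation's scipy calls.
"""

import numpy as np
import pytest
from scipy import stats

from glycomsi import group_stats

# three groups x five observations, unequal means and spread
FIXTURE = {
    "gc": [10.2, 11.1, 9.8, 10.5, 10.9],
    "el": [12.4, 13.0, 12.1, 12.8, 13.3],
    "h": [8.1, 7.9, 8.4, 8.0, 8.6],
}


def oracle_one_way(groups):
    """F statistic, p, and Tukey adjusted p computed from first principles."""
    samples = [np.asarray(v, float) for v in groups.values()]
    k = len(samples)
    n_total = sum(len(s) for s in samples)
    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, n_total - k
    f = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(f, df_b, df_w)
    mse = ss_within / df_w
    tukey = {}
    names = list(groups)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = samples[i], samples[j]
            se = np.sqrt(mse / 2 * (1 / len(a) + 1 / len(b)))
            q = abs(a.mean() - b.mean()) / se
            tukey[(names[i], names[j])] = stats.studentized_range.sf(q, k, df_w)
    return f, p, tukey


def test_one_way_matches_first_principles_oracle():
    f, p, tukey = oracle_one_way(FIXTURE)
    res = group_stats.one_way_anova_tukey(FIXTURE)
    assert res.statistic == pytest.approx(f, abs=1e-6)
    assert res.p_value == pytest.approx(p, abs=1e-6)
    for _, row in res.pairwise.iterrows():
        assert row["adj_p"] == pytest.approx(
            tukey[(row["group_a"], row["group_b"])], abs=1e-6)


def test_one_way_two_groups_equals_squared_t():
    """With two groups, ANOVA F equals the pooled two-sample t squared."""
    a, b = FIXTURE["gc"], FIXTURE["h"]
    res = group_stats.one_way_anova_tukey({"a": a, "b": b})
    t, p = stats.ttest_ind(a, b, equal_var=True)
    assert res.statistic == pytest.approx(t ** 2, rel=1e-10)
    assert res.p_value == pytest.approx(p, rel=1e-10)


def test_one_way_degenerate_design_errors():
    with pytest.raises(ValueError, match="degenerate"):
        group_stats.one_way_anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})


def test_one_way_preconditions():
    with pytest.raises(ValueError):
        group_stats.one_way_anova_tukey({"a": [1.0, 2.0]})
    with pytest.raises(ValueError, match="n < 2"):
        group_stats.one_way_anova_tukey({"a": [1.0], "b": [2.0, 3.0]})
    with pytest.raises(ValueError, match="finite"):
        group_stats.one_way_anova_tukey({"a": [1.0, np.nan], "b": [2.0, 3.0]})


def test_tukey_adjusted_p_at_least_unadjusted():
    """Adjusted p exceeds the unadjusted p of the same pooled-MSE contrast."""
    res = group_stats.one_way_anova_tukey(FIXTURE)
    samples = {k: np.asarray(v, float) for k, v in FIXTURE.items()}
    k = len(samples)
    n_total = sum(len(s) for s in samples.values())
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples.values()) \
        / (n_total - k)
    for _, row in res.pairwise.iterrows():
        a, b = samples[row["group_a"]], samples[row["group_b"]]
        t = abs(a.mean() - b.mean()) / np.sqrt(mse * (1 / len(a) + 1 / len(b)))
        raw_p = 2 * stats.t.sf(t, n_total - k)
        assert row["adj_p"] >= raw_p - 1e-12
        assert 0.0 <= row["adj_p"] <= 1.0


def test_significance_star_bands():
    assert group_stats.significance_stars(0.03) == "*"
    assert group_stats.significance_stars(0.005) == "**"
    assert group_stats.significance_stars(5e-4) == "***"
    assert group_stats.significance_stars(5e-5) == "****"
    assert group_stats.significance_stars(0.2) == "ns"


# --- two-way ---------------------------------------------------------------

def two_way_fixture(interaction=0.0, noise_sd=0.0, seed=5):
    rng = np.random.default_rng(seed)
    regions = ["t", "s"]
    dps = [4, 5, 6]
    vals, fa, fb = [], [], []
    for i, r in enumerate(regions):
        for j, dp in enumerate(dps):
            for _ in range(3):
                mu = 2.0 * i + 0.5 * j + interaction * i * j
                vals.append(mu + rng.normal(0, noise_sd))
                fa.append(r)
                fb.append(dp)
    return vals, fa, fb


def test_two_way_additive_noiseless_interaction_near_zero():
    """Exactly additive cell means (with symmetric replicate spread) give an
    interaction F of zero."""
    vals, fa, fb = [], [], []
    for i, r in enumerate(["t", "s"]):
        for j, dp in enumerate([4, 5, 6]):
            mu = 2.0 * i + 0.5 * j
            for offset in (-0.1, 0.0, 0.1):  # cell mean stays exactly mu
                vals.append(mu + offset)
                fa.append(r)
                fb.append(dp)
    res = group_stats.two_way_anova_tukey(vals, fa, fb)
    assert res.statistic == pytest.approx(0.0, abs=1e-10)


def test_two_way_matches_statsmodels_cellwise_oracle():
    """Within-level Tukey p from the pooled MSE agrees with a direct
    studentized-range computation on the same cells."""
    vals, fa, fb = two_way_fixture(interaction=0.8, noise_sd=0.3)
    res = group_stats.two_way_anova_tukey(vals, fa, fb)
    df = {"v": np.asarray(vals), "a": np.asarray(fa), "b": np.asarray(fb)}
    # independent residual MSE: subtract cell means
    resid_ss, n, cells = 0.0, len(vals), 0
    for a in set(fa):
        for b in set(fb):
            sel = (df["a"] == a) & (df["b"] == b)
            resid_ss += ((df["v"][sel] - df["v"][sel].mean()) ** 2).sum()
            cells += 1
    mse = resid_ss / (n - cells)
    df_resid = n - cells
    for _, row in res.pairwise.iterrows():
        sa = df["v"][(df["a"] == row["group_a"]) & (df["b"] == row["factor_b"])]
        sb = df["v"][(df["a"] == row["group_b"]) & (df["b"] == row["factor_b"])]
        se = np.sqrt(mse / 2 * (1 / len(sa) + 1 / len(sb)))
        q = abs(sa.mean() - sb.mean()) / se
        expect = stats.studentized_range.sf(q, 2, df_resid)
        assert row["adj_p"] == pytest.approx(expect, abs=1e-6)


def test_two_way_pairwise_covers_each_b_level():
    vals, fa, fb = two_way_fixture(noise_sd=0.2)
    res = group_stats.two_way_anova_tukey(vals, fa, fb)
    assert sorted(res.pairwise["factor_b"].unique()) == [4, 5, 6]


def test_two_way_empty_cell_errors():
    vals, fa, fb = two_way_fixture(noise_sd=0.2)
    keep = [not (a == "t" and b == 5) for a, b in zip(fa, fb)]
    with pytest.raises(ValueError, match="cells"):
        group_stats.two_way_anova_tukey(
            [v for v, k in zip(vals, keep) if k],
            [a for a, k in zip(fa, keep) if k],
            [b for b, k in zip(fb, keep) if k])


# --- t-tests ---------------------------------------------------------------

def test_identical_paired_samples_give_p_one():
    res = group_stats.t_test_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                        paired=True)
    assert res.p_value == 1.0
    assert res.flags


def test_welch_and_pooled_differ_on_heteroscedastic_data():
    a = [10.0, 10.1, 9.9, 10.2, 9.8]
    b = [12.0, 8.0, 15.0, 5.0, 14.0, 6.0, 13.0]
    welch = group_stats.t_test_two_tailed(a, b)
    pooled = group_stats.t_test_two_tailed(a, b, pooled=True)
    tw, pw = stats.ttest_ind(a, b, equal_var=False)
    assert welch.p_value == pytest.approx(pw, rel=1e-12)
    assert welch.p_value != pytest.approx(pooled.p_value, rel=1e-3)


def test_t_test_power_close_to_nominal(rng):
    """Power at a computed effect size is near the analytic value."""
    n, delta, sd = 12, 1.0, 1.0
    df = 2 * n - 2
    ncp = delta / (sd * np.sqrt(2 / n))
    crit = stats.t.ppf(0.975, df)
    analytic = stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)
    reps = 1500
    hits = 0
    for _ in range(reps):
        a = rng.normal(0, sd, n)
        b = rng.normal(delta, sd, n)
        if group_stats.t_test_two_tailed(a, b, pooled=True).p_value < 0.05:
            hits += 1
    assert hits / reps == pytest.approx(analytic, abs=0.04)


def test_zero_variance_unpaired_conventions():
    equal = group_stats.t_test_two_tailed([2.0, 2.0], [2.0, 2.0])
    assert equal.p_value == 1.0 and equal.flags
    diff = group_stats.t_test_two_tailed([2.0, 2.0], [3.0, 3.0])
    assert diff.p_value == 0.0 and diff.flags
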