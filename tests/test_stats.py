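"""Unit and property tests for the inferential battery.

Each hand-written statistic is checked three ways where possible: against the
published summary numbers it must reproduce, against an independent library
oracle (scipy / statsmodels / pingouin), and against the algebraic identities
that define it.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from bhq import stats as S

finite_floats = st.floats(-50, 50, allow_nan=False)


def make_frame(pre1, post1, pre2, post2, measure="m"):
    rows = []
    for g, pre, post in (("intervention", pre1, post1), ("control", pre2, post2)):
        for j, (a, b) in enumerate(zip(pre, post)):
            pid = f"{g[:1]}{j}"
            rows.append((pid, g, "pre", measure, a))
            rows.append((pid, g, "post", measure, b))
    return pd.DataFrame(rows, columns=["participant", "group", "time", "measure", "value"])


# ---------------------------------------------------------------------------
# two-sample t


@pytest.mark.parametrize(
    "m1, s1, m2, s2, expected_t",
    [
        (95.445, 4.254, 97.476, 3.507, 2.179),  # baseline whole-brain FA quotient
        (31.641, 17.726, 24.031, 10.244, -2.199),  # baseline TMT B-A
        (95.574, 4.452, 98.038, 3.986, 2.439),  # baseline cingulum quotient
        (96.276, 7.614, 96.983, 7.120, 0.401),  # baseline GM quotient
    ],
)
def test_two_sample_t_reproduces_published_baselines(m1, s1, m2, s2, expected_t):
    res = S.two_sample_t(mean1=m1, sd1=s1, n1=35, mean2=m2, sd2=s2, n2=35)
    assert res.statistic == pytest.approx(expected_t, abs=5e-4)
    assert res.df == 68


def test_two_sample_t_equal_means_is_zero():
    res = S.two_sample_t(mean1=5.0, sd1=1.0, n1=10, mean2=5.0, sd2=2.0, n2=12)
    assert res.statistic == 0.0
    assert res.p_two_sided == 1.0


def test_two_sample_t_degenerate_raises():
    with pytest.raises(ValueError):
        S.two_sample_t(mean1=1.0, sd1=0.0, n1=5, mean2=1.0, sd2=0.0, n2=5)


def test_two_sample_t_vector_path_matches_scipy_and_summary_path(rng):
    x = rng.normal(0, 1, 9)
    y = rng.normal(0.5, 1.4, 13)
    mine = S.two_sample_t(x, y)
    ref_t, ref_p = sps.ttest_ind(y, x)
    assert mine.statistic == pytest.approx(ref_t, rel=1e-12)
    assert mine.p_two_sided == pytest.approx(ref_p, rel=1e-12)
    summary = S.two_sample_t(
        mean1=x.mean(), sd1=x.std(ddof=1), n1=x.size, mean2=y.mean(), sd2=y.std(ddof=1), n2=y.size
    )
    assert summary.statistic == pytest.approx(mine.statistic, rel=1e-12)
    welch = S.two_sample_t(x, y, welch=True)
    ref_t_w, ref_p_w = sps.ttest_ind(y, x, equal_var=False)
    assert welch.statistic == pytest.approx(ref_t_w, rel=1e-12)
    assert welch.p_two_sided == pytest.approx(ref_p_w, rel=1e-10)


# ---------------------------------------------------------------------------
# paired t


@pytest.mark.parametrize("t, expected_d", [(2.078, 0.351), (1.281, 0.217)])
def test_paired_d_from_t_matches_published(t, expected_d):
    assert t / math.sqrt(35) == pytest.approx(expected_d, abs=5e-4)


def test_paired_t_identical_vectors():
    res = S.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0
    assert res.effect_size == 0.0


def test_paired_t_matches_scipy_and_d_identity(rng):
    pre = rng.normal(100, 4, 20)
    post = pre + rng.normal(0.5, 1.5, 20)
    res = S.paired_t(pre, post)
    ref_t, ref_p = sps.ttest_rel(pre, post)
    assert res.statistic == pytest.approx(ref_t, rel=1e-12)
    assert res.p_two_sided == pytest.approx(ref_p, rel=1e-12)
    assert res.effect_size == pytest.approx(res.statistic / math.sqrt(20), rel=1e-15)


def test_paired_t_constant_nonzero_difference_raises():
    with pytest.raises(ValueError, match="infinite"):
        S.paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.tuples(finite_floats, finite_floats), min_size=3, max_size=30))
def test_paired_t_effect_size_identity_property(pairs):
    pre = np.array([a for a, _ in pairs])
    post = np.array([b for _, b in pairs])
    if np.std(pre - post, ddof=1) == 0:
        return
    res = S.paired_t(pre, post)
    assert res.effect_size == pytest.approx(res.statistic / math.sqrt(len(pairs)), rel=1e-12)


# ---------------------------------------------------------------------------
# mixed ANOVA interaction


def test_interaction_equals_squared_change_t(rng):
    pre1, pre2 = rng.normal(95, 4, 35), rng.normal(97, 4, 35)
    post1 = pre1 + rng.normal(0.5, 1.5, 35)
    post2 = pre2 + rng.normal(-0.4, 1.5, 35)
    frame = make_frame(pre1, post1, pre2, post2)
    anova = S.mixed_anova_2x2(frame, "m")
    t_change = S.two_sample_t(post1 - pre1, post2 - pre2)
    assert anova.statistic == pytest.approx(t_change.statistic**2, rel=1e-10)
    assert anova.df == (1.0, 68.0)
    assert anova.p_two_sided == pytest.approx(t_change.p_two_sided, rel=1e-10)


def test_interaction_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    pre1, pre2 = rng.normal(95, 4, 12), rng.normal(97, 4, 14)
    post1 = pre1 + rng.normal(1.0, 1.5, 12)
    post2 = pre2 + rng.normal(0.0, 1.5, 14)
    frame = make_frame(pre1, post1, pre2, post2)
    mine = S.mixed_anova_2x2(frame, "m")
    ref = pingouin.mixed_anova(
        data=frame, dv="value", within="time", subject="participant", between="group"
    )
    ref_f = float(ref.loc[ref["Source"] == "Interaction", "F"].iloc[0])
    assert mine.statistic == pytest.approx(ref_f, rel=1e-8)


def test_interaction_null_when_groups_shift_equally():
    pre = np.arange(10, dtype=float)
    frame = make_frame(pre, pre + 2.0 + 0.01 * pre, pre, pre + 2.0 + 0.01 * pre)
    anova = S.mixed_anova_2x2(frame, "m")
    assert anova.statistic == pytest.approx(0.0, abs=1e-20)


def test_interaction_published_effect_size():
    assert S.partial_eta_squared(5.292, 1, 68) == pytest.approx(0.072, abs=5e-4)
    assert S.partial_eta_squared(6.605, 1, 68) == pytest.approx(0.089, abs=5e-4)


def test_partial_eta_squared_boundaries():
    assert S.partial_eta_squared(0.0, 1, 68) == 0.0
    assert S.partial_eta_squared(34.0, 2, 68) == pytest.approx(0.5)
    etas = [S.partial_eta_squared(f, 1, 68) for f in (0.5, 1.0, 2.0, 8.0)]
    assert all(a < b for a, b in zip(etas, etas[1:]))
    assert all(0 < e < 1 for e in etas)


# ---------------------------------------------------------------------------
# correlations


def test_change_correlation_published_p():
    # r = .359 at n = 35 must round to the published p = .034
    t = 0.359 * math.sqrt(33) / math.sqrt(1 - 0.359**2)
    p = 2 * sps.t.sf(t, 33)
    assert round(p, 3) == 0.034
    x = np.arange(10.0)
    res = S.pearson_change_correlation(x, 2 * x + 1)
    assert res.extra["r"] == pytest.approx(1.0)


def test_change_correlation_matches_scipy(rng):
    x, y = rng.normal(0, 1, 25), rng.normal(0, 1, 25)
    res = S.pearson_change_correlation(x, y)
    ref = sps.pearsonr(x, y)
    assert res.extra["r"] == pytest.approx(ref.statistic, rel=1e-12)
    assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)


def test_change_correlation_constant_input_raises():
    with pytest.raises(ValueError):
        S.pearson_change_correlation([1.0] * 6, [1, 2, 3, 4, 5, 6])


@pytest.mark.parametrize(
    "r1, r2, expected_z",
    [
        (0.359, -0.286, 2.680),  # vigor coupling, intervention vs control
        (-0.353, 0.058, -1.708),  # TMT B vs internal capsule
        (-0.335, 0.062, -1.642),  # TMT B vs corpus callosum
    ],
)
def test_fisher_z_reproduces_published(r1, r2, expected_z):
    cmp_ = S.fisher_z_compare(r1, 35, r2, 35)
    assert cmp_.z == pytest.approx(expected_z, abs=5e-4)


def test_fisher_z_antisymmetry_and_null(rng):
    assert S.fisher_z_compare(0.4, 20, 0.4, 20).z == 0.0
    a = S.fisher_z_compare(0.52, 30, -0.11, 44)
    b = S.fisher_z_compare(-0.11, 44, 0.52, 30)
    assert a.z == pytest.approx(-b.z, rel=1e-14)
    assert a.p_two_sided == pytest.approx(2 * a.p_one_sided, rel=1e-14)
    with pytest.raises(ValueError):
        S.fisher_z_compare(1.0, 10, 0.0, 10)


# ---------------------------------------------------------------------------
# multiple comparisons


def _bh_bruteforce(p, q):
    p = np.asarray(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_idx in range(m):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_idx, m)]
        adj[order[rank_idx]] = min(1.0, min(candidates))
    return adj, adj <= q


def test_bh_matches_bruteforce_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(10):
        p = rng.uniform(0, 1, rng.integers(1, 12))
        adj, rej = S.benjamini_hochberg(p, 0.05)
        badj, brej = _bh_bruteforce(p, 0.05)
        assert np.allclose(adj, badj)
        assert np.array_equal(rej, brej)
        sm_rej, sm_adj, *_ = multipletests(p, 0.05, method="fdr_bh")
        assert np.allclose(adj, sm_adj)
        assert np.array_equal(rej, sm_rej)


def test_bh_permutation_invariance_and_trivials(rng):
    p = rng.uniform(0, 1, 8)
    adj, _ = S.benjamini_hochberg(p)
    perm = rng.permutation(8)
    adj_p, _ = S.benjamini_hochberg(p[perm])
    assert np.allclose(adj[perm], adj_p)
    assert S.benjamini_hochberg([0.03])[0][0] == pytest.approx(0.03)
    adj_eq, _ = S.benjamini_hochberg([0.2, 0.2, 0.2])
    assert np.allclose(adj_eq, 0.2)


def test_bh_superset_of_bonferroni(rng):
    for _ in range(20):
        p = rng.uniform(0, 0.2, 8)
        _, bh_rej = S.benjamini_hochberg(p, 0.05)
        bonf_rej = p <= 0.05 / p.size
        assert np.all(bh_rej[bonf_rej])


def test_bh_reproduces_published_regional_significance():
    """Six of eight regional interaction p-values survive BH at the 5% level."""
    pvals = [0.012, 0.014, 0.024, 0.027, 0.030, 0.056, 0.017, 0.093]
    adj, rej = S.benjamini_hochberg(pvals, 0.05)
    assert int(rej.sum()) == 6
    assert not rej[5] and not rej[7]  # cingulum and uncinate fasciculus


# ---------------------------------------------------------------------------
# chi-square, power, TMT


def test_chi_square_published_sex_table():
    res = S.chi_square_2x2(14, 21, 17, 18)
    assert res.statistic == pytest.approx(0.521, abs=5e-4)
    assert res.p_two_sided == pytest.approx(0.470, abs=5e-4)


def test_chi_square_proportional_table_is_zero():
    assert S.chi_square_2x2(10, 20, 5, 10).statistic == 0.0
    with pytest.raises(ValueError):
        S.chi_square_2x2(0, 0, 5, 10)


def test_chi_square_matches_scipy(rng):
    a, b, c, d = rng.integers(1, 40, 4)
    res = S.chi_square_2x2(a, b, c, d)
    ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)
    assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
    assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)


def test_power_sample_size_published_and_boundary():
    assert S.power_paired_n(0.5, 0.05, 0.80) == 34
    assert S.power_paired_n(50.0, 0.05, 0.80) == 2
    with pytest.raises(ValueError):
        S.power_paired_n(0.0)


def test_power_is_monotone_in_n():
    powers = [S.paired_t_power(n, 0.3) for n in range(2, 201)]
    assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))
    n = S.power_paired_n(0.3)
    assert S.paired_t_power(n, 0.3) >= 0.80 > S.paired_t_power(n - 1, 0.3)


def test_tmt_difference_paths():
    assert S.tmt_b_minus_a(51.867, 22.640) == pytest.approx(29.227)
    assert S.tmt_b_minus_a(10.0, 10.0) == 0.0
    b = np.array([30.0, 40.0, 50.0])
    a = np.array([10.0, 15.0, 20.0])
    # vector path is linear: mean of differences equals difference of means
    assert S.tmt_b_minus_a(b, a).mean() == pytest.approx(b.mean() - a.mean())
    with pytest.raises(ValueError):
        S.tmt_b_minus_a(-1.0, 2.0)
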