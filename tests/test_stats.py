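"""Hypothesis tests vs independent oracles; BH adjustment; power search."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from intronflank.position_profile import PositionProfile
from intronflank.stats import (bh_adjust, bh_adjust_vector,
                               flanking_vs_exonic_fp_test, paired_t_power,
                               pairwise_count_ttest, pairwise_fp_fisher,
                               pairwise_matrix, power_sample_size)


# ---------------------------------------------------------------------------
# Fisher's exact: full hypergeometric enumeration oracle


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating every table with the same margins
    and summing the probabilities of those no more likely than observed."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_prob(x):  # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(n, c1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = table_prob(a)
    total = sum(table_prob(x) for x in range(lo, hi + 1)
                if table_prob(x) <= p_obs * (1 + 1e-12))
    return min(total, 1.0)


def _profile_from_counts(cells):
    """cells: {bucket: (pass, false)} -> minimal PositionProfile."""
    W = max(cells)
    df = pd.DataFrame(index=pd.RangeIndex(1, W + 1, name="position"),
                      columns=["raw_count", "pass_count", "false_count"],
                      data=0)
    for d, (p, f) in cells.items():
        df.loc[d] = [p + f, p, f]
    return PositionProfile(per_bucket=df, totals={}, W=W)


@pytest.mark.parametrize("table,expected", [
    (((5, 5), (5, 5)), 1.0),
    (((10, 0), (0, 10)), 2 / math.comb(20, 10)),
    (((3, 1), (1, 3)), 0.4857142857142857),
])
def test_fisher_known_tables(table, expected):
    prof = _profile_from_counts({1: table[0], 2: table[1]})
    assert pairwise_fp_fisher(prof, 1, 2) == pytest.approx(expected, rel=1e-9)
    a, b = table[0]
    c, d = table[1]
    assert fisher_oracle(a, b, c, d) == pytest.approx(expected, rel=1e-9)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.tuples(st.integers(1, 12), st.integers(0, 12),
                 st.integers(1, 12), st.integers(0, 12)))
def test_fisher_matches_enumeration(cells):
    a, b, c, d = cells
    prof = _profile_from_counts({1: (a, b), 2: (c, d)})
    assert pairwise_fp_fisher(prof, 1, 2) == pytest.approx(
        fisher_oracle(a, b, c, d), rel=1e-8, abs=1e-12)


def test_fisher_empty_bucket_missing():
    prof = _profile_from_counts({1: (5, 5), 2: (0, 0)})
    assert np.isnan(pairwise_fp_fisher(prof, 1, 2))


# ---------------------------------------------------------------------------
# t-tests


def test_ttest_identical_columns_zero_variance_missing():
    m = pd.DataFrame({1: [4, 5, 6], 2: [4, 5, 6]})
    assert np.isnan(pairwise_count_ttest(m, 1, 2))


def test_ttest_shifted_columns_highly_significant():
    rng = np.random.default_rng(5)
    base = rng.normal(50, 1, 10)
    m = pd.DataFrame({1: base + 5, 2: base + rng.normal(0, 1, 10)})
    p = pairwise_count_ttest(m, 1, 2)
    assert p < 0.001
    # reference computation: t with n-1 df on the paired differences
    diff = (m[1] - m[2]).to_numpy()
    t = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
    from scipy.stats import t as tdist
    assert p == pytest.approx(2 * tdist.sf(abs(t), len(diff) - 1), rel=1e-9)


def test_ttest_single_sample_errors():
    m = pd.DataFrame({1: [4], 2: [5]})
    with pytest.raises(ValueError):
        pairwise_count_ttest(m, 1, 2)
    with pytest.raises(ValueError):
        pairwise_count_ttest(pd.DataFrame({1: [1, 2], 2: [3, 4]}), 1, 1)


def test_ttest_matches_permutation_approximation():
    rng = np.random.default_rng(42)
    x = rng.normal(10, 2, 12)
    y = x + rng.normal(0.8, 1.0, 12)
    m = pd.DataFrame({1: x, 2: y})
    p = pairwise_count_ttest(m, 1, 2)
    diff = x - y
    t_obs = abs(diff.mean())
    signs = rng.choice([-1, 1], size=(20000, 12))
    perm = np.abs((signs * diff).mean(axis=1))
    p_perm = (perm >= t_obs - 1e-12).mean()
    assert p == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm / 20000) + 0.01)


def test_flanking_vs_exonic_fp():
    rng = np.random.default_rng(3)
    exonic = rng.uniform(0.05, 0.15, 50)
    flanking = exonic + 0.15 + rng.normal(0, 0.02, 50)
    res = flanking_vs_exonic_fp_test(flanking, exonic,
                                     pooled_table=[[300, 200], [450, 50]])
    assert res.t_p < 1e-20
    assert res.fisher_p < 1e-10
    assert res.mean_fp_flanking > res.mean_fp_exonic
    same = flanking_vs_exonic_fp_test(exonic, exonic)
    assert np.isnan(same.t_p)


def test_flanking_vs_exonic_two_samples_one_df():
    # closed form with 1 df: t = dbar / (sd/sqrt(2))
    res = flanking_vs_exonic_fp_test(np.array([0.5, 0.6]),
                                     np.array([0.1, 0.3]))
    d = np.array([0.4, 0.3])
    t = d.mean() / (d.std(ddof=1) / np.sqrt(2))
    from scipy.stats import t as tdist
    assert res.t_p == pytest.approx(2 * tdist.sf(abs(t), 1), rel=1e-9)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_examples():
    assert bh_adjust_vector(np.array([0.01, 0.02, 0.03, 0.04])) == \
        pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert bh_adjust_vector(np.array([0.5])) == pytest.approx([0.5])
    assert bh_adjust_vector(np.array([0.2, 0.2, 0.2])) == \
        pytest.approx([0.2, 0.2, 0.2])


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20),
       st.randoms(use_true_random=False))
def test_bh_permutation_invariant_and_dominates_raw(ps, rnd):
    p = np.array(ps)
    adj = bh_adjust_vector(p)
    assert (adj >= p - 1e-12).all() and (adj <= 1.0 + 1e-12).all()
    perm = list(range(len(ps)))
    rnd.shuffle(perm)
    adj_perm = bh_adjust_vector(p[perm])
    assert adj_perm == pytest.approx(adj[perm])


def test_bh_matrix_symmetric():
    p = pd.DataFrame([[np.nan, 0.01, 0.04],
                      [0.01, np.nan, 0.03],
                      [0.04, 0.03, np.nan]], index=[1, 2, 3], columns=[1, 2, 3])
    adj = bh_adjust(p)
    assert adj.loc[1, 2] == adj.loc[2, 1]
    assert adj.loc[1, 2] == pytest.approx(0.03)  # 0.01*3/1 -> min with later
    assert np.isnan(adj.loc[1, 1])


def test_pairwise_matrix_symmetric_with_nan_diagonal():
    m = pd.DataFrame({1: [1, 2, 3, 4], 2: [2, 3, 4, 6], 3: [1, 1, 1, 1]})
    mat = pairwise_matrix(m, test="t_test")
    assert mat.p.shape == (3, 3)
    assert np.isnan(mat.p.loc[1, 1])
    assert mat.p.loc[1, 2] == mat.p.loc[2, 1]


# ---------------------------------------------------------------------------
# power / sample size


def test_power_sample_size_medium_effect():
    assert power_sample_size("paired_t", 0.5, 0.05, 0.95, 2) == 54
    assert power_sample_size("paired_t", 0.5, 0.05, 0.80, 2) == 34


def test_power_saturates_for_huge_effect():
    n = power_sample_size("paired_t", 10.0, 0.05, 0.80, 2)
    assert n <= 4
    # self-consistency: n is the first integer reaching the target
    assert paired_t_power(n, 10.0) >= 0.80
    assert n == 2 or paired_t_power(n - 1, 10.0) < 0.80


def test_power_monotone_in_effect_alpha_power():
    assert power_sample_size(effect_size=0.8) <= power_sample_size(effect_size=0.5)
    assert power_sample_size(power=0.80) <= power_sample_size(power=0.95)
    assert power_sample_size(alpha=0.05) <= power_sample_size(alpha=0.01)


def test_power_unattainable_errors():
    with pytest.raises(ValueError):
        power_sample_size(effect_size=1e-6, max_n=100)
    with pytest.raises(ValueError):
        power_sample_size(effect_size=-1)


def test_power_matches_monte_carlo():
    # simulate paired t at n=34, dz=0.5: power ~ 0.808
    rng = np.random.default_rng(9)
    n, reps = 34, 4000
    x = rng.normal(0.5, 1.0, size=(reps, n))
    t = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(n))
    from scipy.stats import t as tdist
    crit = tdist.ppf(0.975, n - 1)
    emp = (np.abs(t) > crit).mean()
    assert paired_t_power(n, 0.5) == pytest.approx(emp, abs=0.025)
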