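"""Rank tests, ROC/DeLong and ICC against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from dcebrix.errors import InsufficientDataError, UndefinedROCError
from dcebrix.stats import (
    delong_compare,
    group_comparison_table,
    icc_intrarater,
    kruskal_wallis,
    rank_test,
    roc_auc,
)


def exact_mwu_pvalue(a, b):
    """Two-sided Mann-Whitney p by full enumeration of rank assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = a.size, b.size
    observed = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    mean_u = n * m / 2.0
    obs_dev = abs(observed - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        u = sum(
            (pooled[i] > pooled[j]) + 0.5 * (pooled[i] == pooled[j])
            for i in idx
            for j in range(n + m)
            if j not in idx
        )
        total += 1
        if abs(u - mean_u) >= obs_dev - 1e-12:
            count += 1
    return count / total


def pair_count_auc(scores, labels):
    """O(n^2) concordant-pair AUC: (concordant + ties/2) / (n1*n2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    grid = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return float(grid.sum() / (pos.size * neg.size))


def test_identical_groups_give_p_one():
    assert rank_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_fully_separated_small_groups():
    assert rank_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)


def test_rank_test_matches_enumeration(rng):
    for n, m in [(3, 4), (4, 4), (3, 5)]:
        a = rng.normal(size=n)
        b = rng.normal(loc=0.8, size=m)
        assert rank_test(a, b) == pytest.approx(exact_mwu_pvalue(a, b),
                                                abs=1e-12)


def test_rank_test_needs_two_per_group():
    with pytest.raises(InsufficientDataError):
        rank_test([1.0], [2.0, 3.0])


def test_kruskal_two_groups_equals_rank_sum(rng):
    """For 2 tie-free groups KW reduces to the (uncorrected) rank-sum test."""
    a, b = rng.normal(size=8), rng.normal(loc=0.5, size=10)
    p_kw = kruskal_wallis(a, b)
    p_mw = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                        use_continuity=False).pvalue
    assert p_kw == pytest.approx(p_mw, rel=1e-10)


def test_kruskal_three_groups(rng):
    p = kruskal_wallis(rng.normal(size=10), rng.normal(size=10),
                       rng.normal(loc=3.0, size=10))
    assert p < 0.01


def test_auc_perfect_separation():
    auc, _ = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert auc == 1.0


def test_auc_null_calibration(rng):
    scores = rng.normal(size=200)
    labels = rng.random(200) < 0.5
    auc, (lo, hi) = roc_auc(scores, labels)
    assert 0.4 < auc < 0.6
    assert lo < 0.5 < hi


def test_auc_matches_pair_counting(rng):
    for _ in range(10):
        n = int(rng.integers(10, 50))
        scores = np.round(rng.normal(size=n), 1)  # induce ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            continue
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)


def test_auc_complement_symmetry(rng):
    scores = rng.normal(size=40)
    labels = rng.random(40) < 0.5
    a1, _ = roc_auc(scores, labels)
    a2, _ = roc_auc(-scores, labels)
    assert a1 + a2 == pytest.approx(1.0, abs=1e-12)


def test_auc_requires_both_classes():
    with pytest.raises(UndefinedROCError):
        roc_auc([1.0, 2.0], [1, 1])


def test_delong_identical_scores_p_one(rng):
    s = rng.normal(size=30)
    y = rng.random(30) < 0.5
    assert delong_compare(s, s, y) == 1.0


def test_delong_monotone_transform_p_one(rng):
    s = rng.normal(size=30)
    y = rng.random(30) < 0.5
    assert delong_compare(s, np.exp(s), y) == pytest.approx(1.0)


def test_delong_rejects_unpaired():
    with pytest.raises(ValueError):
        delong_compare([1, 2, 3], [1, 2], [0, 1, 1])


def test_delong_matches_paired_bootstrap():
    """DeLong p lands inside the Monte-Carlo CI of a paired bootstrap test."""
    rng = np.random.default_rng(42)
    n = 80
    y = np.arange(n) % 2 == 0
    s1 = y * 1.0 + rng.normal(0, 1.0, n)
    s2 = 0.5 * s1 + y * 0.4 + rng.normal(0, 1.0, n)
    p_delong = delong_compare(s1, s2, y)

    boots = 10_000
    diffs = np.empty(boots)
    for b in range(boots):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.all() or not yb.any():
            diffs[b] = 0.0
            continue
        diffs[b] = pair_count_auc(s1[idx], yb) - pair_count_auc(s2[idx], yb)
    # normal-theory two-sided p using the bootstrap SE of the AUC difference
    obs = pair_count_auc(s1, y) - pair_count_auc(s2, y)
    from scipy.stats import norm

    p_boot = 2 * norm.sf(abs(obs) / diffs.std(ddof=1))
    assert p_delong == pytest.approx(p_boot, abs=0.05)


def test_icc_identical_ratings_is_one():
    base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    icc, ci, interp = icc_intrarater(np.c_[base, base])
    assert icc == 1.0 and interp == "excellent"


def test_icc_matches_anova_mean_squares():
    """Two-way absolute-agreement single-measure ICC vs hand ANOVA."""
    table = np.array([[9.0, 10.0], [11.0, 13.0], [14.0, 15.0],
                      [20.0, 18.0], [24.0, 25.0]])
    n, k = table.shape
    grand = table.mean()
    ms_rows = k * np.sum((table.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((table.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum(
        (table - table.mean(1, keepdims=True) - table.mean(0) + grand) ** 2
    )
    ms_err = sse / ((n - 1) * (k - 1))
    expected = (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err)
    )
    icc, _, _ = icc_intrarater(table)
    assert icc == pytest.approx(expected, rel=1e-6)


def test_icc_interpretation_spans_ci_bands(rng):
    """A wide CI is reported as the range of agreement bands it spans."""
    subj = rng.normal(20, 5, 6)
    ratings = np.c_[subj + rng.normal(0, 1.2, 6), subj + rng.normal(0, 1.2, 6)]
    icc, (lo, hi), interp = icc_intrarater(ratings)
    assert lo <= icc <= hi
    if " to " in interp:
        first, last = interp.split(" to ")
        order = ["poor", "moderate", "good", "excellent"]
        assert order.index(first) < order.index(last)


def test_icc_needs_five_subjects():
    with pytest.raises(InsufficientDataError):
        icc_intrarater(np.array([[1.0, 1.1], [2.0, 2.1]]))


def test_type_one_error_at_study_group_sizes(rng):
    """Null rejection rate of the rank test at n = 7 vs 15 is near 0.05."""
    sims = 10_000
    rejections = 0
    for _ in range(sims):
        if rank_test(rng.normal(size=7), rng.normal(size=15)) < 0.05:
            rejections += 1
    rate = rejections / sims
    se = np.sqrt(0.05 * 0.95 / sims)
    assert abs(rate - 0.05) < 3 * se + 0.005


def test_group_comparison_table_structure(feature_table):
    table = group_comparison_table(
        feature_table, feature_table["label"],
        parameters=["TTP", "wash_out", "kep"],
    )
    assert list(table["parameter"]) == ["TTP", "wash_out", "kep"]
    assert ((table["p_value"] >= 0) & (table["p_value"] <= 1)).all()
    assert ((table["auc_roc"] >= 0.5) & (table["auc_roc"] <= 1)).all()
    # calibrated cohorts separate on TTP more than on kep
    ttp_auc = float(table.set_index("parameter").loc["TTP", "auc_roc"])
    kep_auc = float(table.set_index("parameter").loc["kep", "auc_roc"])
    assert ttp_auc > kep_auc
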