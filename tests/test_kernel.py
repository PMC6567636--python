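"""Kernel correctness: merge-scan counting, null moments, standardization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from jtscan.kernel import (
    OpCounter,
    Status,
    brute_force_jt,
    jt_statistic,
    jt_test,
    mann_whitney_count,
    null_moments,
    permutation_null_exhaustive,
    sort_into_groups,
    tie_block_sizes,
)

# --- strategies -----------------------------------------------------------

# small integer-valued traits force heavy ties
tied_values = st.lists(st.integers(min_value=0, max_value=6), min_size=0, max_size=40)
labels_for = lambda n, t: st.lists(
    st.integers(min_value=0, max_value=t - 1), min_size=n, max_size=n
)


@st.composite
def labelled_instance(draw, max_n=40, max_t=5):
    n = draw(st.integers(min_value=0, max_value=max_n))
    t = draw(st.integers(min_value=2, max_value=max_t))
    values = draw(st.lists(
        st.one_of(st.integers(min_value=-3, max_value=3),
                  st.floats(allow_nan=False, allow_infinity=False,
                            min_value=-10, max_value=10)),
        min_size=n, max_size=n))
    labs = draw(labels_for(n, t))
    return values, labs


# --- grouping -------------------------------------------------------------

def test_sort_into_groups_partitions_and_sorts():
    g = sort_into_groups([3, 1, 4, 2], [1, 0, 1, 0])
    assert [list(grp) for grp in g.groups] == [[1, 2], [3, 4]]
    assert list(g.level_codes) == [0, 1]
    assert g.n_total == 4


def test_sort_into_groups_single_level():
    g = sort_into_groups([1, 2], [0, 0])
    assert [list(grp) for grp in g.groups] == [[1, 2]]


def test_sort_into_groups_drops_missing():
    g = sort_into_groups([1.0, np.nan, 3.0, 4.0], [0, 0, -1, 1])
    assert g.n_total == 2
    assert [list(grp) for grp in g.groups] == [[1.0], [4.0]]


@given(labelled_instance())
def test_grouping_preserves_multiset(inst):
    values, labs = inst
    g = sort_into_groups(values, labs)
    pooled = np.concatenate([np.asarray(x, float) for x in g.groups]) \
        if g.groups else np.empty(0)
    assert np.array_equal(np.sort(pooled), np.sort(np.asarray(values, float)))
    for grp in g.groups:
        assert np.all(np.diff(grp) >= 0)


# --- Mann-Whitney merge scan ---------------------------------------------

@pytest.mark.parametrize(
    "y1, y2, expected",
    [
        ([1, 2], [3, 4], 4.0),
        ([3, 4], [1, 2], 0.0),
        ([1, 1], [1, 1], 2.0),
        ([], [1, 2], 0.0),
        ([1, 2], [], 0.0),
        ([1, 2, 2, 3], [2, 2, 4], 8.0),
    ],
)
def test_mann_whitney_count_examples(y1, y2, expected):
    assert mann_whitney_count(y1, y2) == expected


@given(tied_values, tied_values)
def test_mann_whitney_matches_double_loop(y1, y2):
    y1, y2 = sorted(y1), sorted(y2)
    brute = sum(
        1.0 if a < b else (0.5 if a == b else 0.0) for a in y1 for b in y2
    )
    assert mann_whitney_count(y1, y2) == brute


@given(tied_values, tied_values)
def test_mann_whitney_work_bound(y1, y2):
    y1, y2 = sorted(y1), sorted(y2)
    c = OpCounter()
    mann_whitney_count(y1, y2, counter=c)
    assert c.merge_steps <= len(y1) + len(y2)


@given(st.lists(st.integers(0, 8), min_size=1, max_size=30),
       st.lists(st.integers(0, 8), min_size=1, max_size=30))
def test_mann_whitney_agrees_with_scipy(y1, y2):
    y1, y2 = sorted(y1), sorted(y2)
    # scipy's U for (y2, y1) counts pairs where the y2 element is larger
    u_scipy = mannwhitneyu(y2, y1, alternative="two-sided").statistic
    assert mann_whitney_count(y1, y2) == pytest.approx(u_scipy)


# --- JT statistic vs brute force -----------------------------------------

@pytest.mark.parametrize(
    "values, labels, expected",
    [
        ([1, 2, 3, 4], [0, 0, 1, 1], 4.0),
        ([1, 2, 3], [0, 1, 2], 3.0),
    ],
)
def test_jt_statistic_examples(values, labels, expected):
    assert jt_statistic(sort_into_groups(values, labels)) == expected
    assert brute_force_jt(values, labels) == expected


@given(labelled_instance())
def test_jt_equals_brute_force(inst):
    values, labs = inst
    assert jt_statistic(sort_into_groups(values, labs)) == \
        brute_force_jt(values, labs)


@given(labelled_instance(max_t=4))
def test_complementarity_under_level_reversal(inst):
    """Reversing the ordinal order maps J to (total pairs) - J."""
    values, labs = inst
    g = sort_into_groups(values, labs)
    sizes = g.group_sizes
    total_pairs = (int(sizes.sum()) ** 2 - int((sizes**2).sum())) / 2
    rev = [max(labs, default=0) - l for l in labs]
    assert jt_statistic(sort_into_groups(values, rev)) == \
        pytest.approx(total_pairs - jt_statistic(g))


@given(labelled_instance())
def test_monotone_invariance(inst):
    """J is a rank statistic: strictly increasing transforms leave it fixed."""
    values, labs = inst
    # round so increments stay resolvable in double precision
    v = np.round(np.asarray(values, float), 2)
    transformed = np.exp(v / 10.0) + 3.0 * v
    assert jt_statistic(sort_into_groups(transformed, labs)) == \
        jt_statistic(sort_into_groups(v, labs))


# --- tie blocks and null moments -----------------------------------------

@pytest.mark.parametrize(
    "values, expected",
    [([1, 2, 3], [1, 1, 1]), ([1, 1, 2, 2, 2], [2, 3]), ([], [])],
)
def test_tie_block_sizes_examples(values, expected):
    assert sorted(tie_block_sizes(values)) == sorted(expected)


@given(st.lists(st.integers(0, 5), max_size=50))
def test_tie_block_sizes_match_frequency_table(values):
    sizes = tie_block_sizes(values)
    assert int(np.sum(sizes)) == len(values)
    from collections import Counter
    assert sorted(sizes) == sorted(Counter(values).values())


def test_null_moments_closed_forms():
    m = null_moments([1, 1], [1, 1])
    assert (m.e0, m.var0) == (0.5, 0.25)
    m = null_moments([2, 2], [1, 1, 1, 1])
    assert m.e0 == 2.0
    assert m.var0 == pytest.approx(5.0 / 3.0, rel=1e-15)


def test_null_moments_no_ties_reduction():
    """With all tie blocks of size 1 the classical no-ties form holds."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        sizes = rng.integers(1, 8, size=rng.integers(2, 5))
        n = int(sizes.sum())
        m = null_moments(sizes, np.ones(n, dtype=int))
        no_ties = (n**2 * (2 * n + 3) -
                   sum(s**2 * (2 * s + 3) for s in sizes)) / 72.0
        assert m.var0 == pytest.approx(no_ties, rel=1e-13)


def test_null_moments_all_tied_is_degenerate():
    m = null_moments([3, 2], [5])
    assert m.var0 == 0.0


def test_permutation_oracle_matches_moments_with_ties():
    vals = [1.0, 1.0, 2.0]
    dist = permutation_null_exhaustive(vals, [2, 1])
    m = null_moments([2, 1], tie_block_sizes(vals))
    assert dist.mean() == pytest.approx(m.e0, rel=1e-12)
    assert dist.var() == pytest.approx(m.var0, rel=1e-12)


def test_permutation_oracle_distribution_2_2():
    dist = permutation_null_exhaustive([1, 2, 3, 4], [2, 2])
    assert sorted(dist) == [0, 1, 2, 2, 3, 4]


def test_permutation_oracle_single_group_degenerate():
    dist = permutation_null_exhaustive([1, 2, 3], [3])
    assert set(dist) == {0.0}


def test_permutation_oracle_refuses_large_n():
    with pytest.raises(ValueError):
        permutation_null_exhaustive(list(range(11)), [5, 6])


# --- end-to-end test ------------------------------------------------------

def test_jt_test_closed_form_example():
    out = jt_test([1, 2, 3, 4], [0, 0, 1, 1])
    assert out.j_stat == 4.0
    assert out.moments.e0 == 2.0
    assert out.moments.var0 == pytest.approx(5.0 / 3.0)
    assert out.z == pytest.approx(2.0 / math.sqrt(5.0 / 3.0), rel=1e-12)
    assert out.p_two_sided == pytest.approx(0.12133525, abs=1e-6)
    assert out.status is Status.OK


def test_jt_test_exhaustive_permutation_pvalue_sanity():
    """The normal approximation should sit near the exact permutation tail."""
    vals = [0.3, 1.2, -0.5, 2.1, 0.8, 1.9]
    labs = [0, 0, 1, 1, 2, 2]
    out = jt_test(vals, labs)
    dist = permutation_null_exhaustive(vals, [2, 2, 2])
    exact_two = np.mean(np.abs(dist - dist.mean()) >=
                        abs(out.j_stat - dist.mean()))
    assert abs(out.p_two_sided - exact_two) < 0.25


def test_jt_test_zero_variance_on_constant_trait():
    out = jt_test([5.0] * 6, [0, 0, 1, 1, 2, 2])
    assert out.status is Status.ZERO_VARIANCE
    assert out.z is None and out.p_two_sided is None


def test_jt_test_degenerate_single_group():
    out = jt_test([1.0, 2.0, 3.0], [1, 1, 1])
    assert out.status is Status.DEGENERATE_GROUPS
    assert out.z is None and out.p_two_sided is None


def test_jt_test_all_missing_is_degenerate():
    out = jt_test([np.nan, np.nan], [0, 1])
    assert out.status is Status.DEGENERATE_GROUPS


def test_one_sided_option():
    out2 = jt_test([1, 2, 3, 4], [0, 0, 1, 1], sided="two")
    out1 = jt_test([1, 2, 3, 4], [0, 0, 1, 1], sided="one")
    assert out1.p_two_sided == pytest.approx(out2.p_two_sided / 2)


def test_textbook_feedback_experiment():
    """Three production groups under increasing feedback (18 workers).

    Classic ordered-alternative example: the published JT statistic is
    J = 79; with the tie-corrected variance the standardized value is
    about 2.04.
    """
    no_info = [40, 35, 38, 43, 44, 41]
    rough = [38, 40, 47, 44, 40, 42]
    accurate = [48, 40, 45, 43, 46, 44]
    values = np.array(no_info + rough + accurate, float)
    labels = np.array([0] * 6 + [1] * 6 + [2] * 6)
    out = jt_test(values, labels)
    assert out.j_stat == 79.0
    assert out.moments.e0 == 54.0
    assert out.moments.var0 == pytest.approx(
        10758 / 72 + 10800 / 176256 + 1980 / 2448, rel=1e-12)
    assert out.z == pytest.approx(2.0393, abs=2e-4)
    assert brute_force_jt(values, labels) == 79.0
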