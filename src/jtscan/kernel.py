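"""Jonckheere-Terpstra (JT) trend-test kernel.

The JT test asks whether a quantitative trait trends monotonically across
the levels of an ordinal feature (e.g. a genotype dosage 0/1/2).  The
statistic is a sum of pairwise Mann-Whitney counts over all ordered pairs
of levels,

    J = sum_{k<l} U_kl,     U_kl = sum_i sum_j phi(y_ik, y_jl),

with phi(a, b) = 1 if a < b, 1/2 if a == b, 0 if a > b.  Under the
permutation null J is asymptotically normal; the standardized statistic
Z = (J - E[J]) / sqrt(Var[J]) uses a tie-corrected null variance.

The point of this module is the *counting algorithm*: with both group
vectors sorted ascending, U_kl is obtained in a single simultaneous pass
over the two vectors (a merge scan), so the per-pair cost is linear in
the number of samples instead of quadratic.  A brute-force double-loop
implementation is provided as a test oracle, together with an exhaustive
permutation-null enumerator used to verify the moment formulas.

All counting is done in doubled units (a strict inequality contributes 2,
a tie contributes 1) so J is exact integer arithmetic until the final
halving.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "MISSING_CODE",
    "Status",
    "OpCounter",
    "GroupedTrait",
    "NullMoments",
    "JTOutcome",
    "sort_into_groups",
    "mann_whitney_count",
    "jt_statistic",
    "tie_block_sizes",
    "null_moments",
    "jt_test",
    "brute_force_jt",
    "permutation_null_exhaustive",
]

#: Sentinel for a missing ordinal code.
MISSING_CODE = -1


class Status(enum.Enum):
    """Validity flag for a single feature-trait test."""

    OK = "OK"
    DEGENERATE_GROUPS = "DEGENERATE_GROUPS"
    ZERO_VARIANCE = "ZERO_VARIANCE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class OpCounter:
    """Instrumentation counter for empirical complexity probes.

    ``merge_steps`` counts pointer advances of the sorted-merge kernel;
    ``pair_comparisons`` counts elementary pairwise comparisons of the
    brute-force kernel.  Both are exact operation counts, independent of
    wall clock.
    """

    __slots__ = ("merge_steps", "pair_comparisons")

    def __init__(self) -> None:
        self.merge_steps = 0
        self.pair_comparisons = 0

    def reset(self) -> None:
        self.merge_steps = 0
        self.pair_comparisons = 0


@dataclass
class GroupedTrait:
    """Per-level sorted trait values for one feature-trait pair.

    ``groups[k]`` holds the trait values of all samples at ordinal level
    ``level_codes[k]``, sorted ascending.  Levels appear in ascending
    code order (the predetermined ordinal order).  Empty groups are
    permitted; they contribute no between-group pairs.
    """

    groups: list
    level_codes: np.ndarray
    n_total: int

    @property
    def group_sizes(self) -> np.ndarray:
        return np.array([len(g) for g in self.groups], dtype=np.int64)

    def pooled_sorted(self) -> np.ndarray:
        """All retained trait values, sorted ascending."""
        if not self.groups:
            return np.empty(0)
        merged = np.concatenate([np.asarray(g, dtype=float) for g in self.groups])
        merged.sort()
        return merged


@dataclass
class NullMoments:
    """Mean and tie-corrected variance of J under the permutation null."""

    e0: float
    var0: float
    n: int
    group_sizes: np.ndarray
    tie_sizes: np.ndarray


@dataclass
class JTOutcome:
    """Result of a single JT test.

    ``z`` and ``p_two_sided`` are ``None`` (never numbers) unless
    ``status`` is ``Status.OK``.
    """

    j_stat: float
    z: Optional[float]
    p_two_sided: Optional[float]
    moments: Optional[NullMoments]
    status: Status
    n_used: int = 0


def _as_float_array(values) -> np.ndarray:
    return np.asarray(values, dtype=float)


def sort_into_groups(values, labels) -> GroupedTrait:
    """Partition trait values by ordinal label, each partition sorted.

    Observations with a missing label (``< 0``) or a missing (NaN) trait
    value are dropped; the rest are grouped by label in ascending numeric
    label order and each group is sorted ascending.
    """
    v = _as_float_array(values)
    lab = np.asarray(labels)
    if v.shape != lab.shape:
        raise ValueError("values and labels must have the same length")
    lab = lab.astype(np.int64, copy=False)
    keep = (lab >= 0) & ~np.isnan(v)
    v, lab = v[keep], lab[keep]
    codes = np.unique(lab)
    groups = [np.sort(v[lab == c]) for c in codes]
    return GroupedTrait(groups=groups, level_codes=codes, n_total=int(v.size))


def mann_whitney_count(y1, y2, counter: Optional[OpCounter] = None) -> float:
    """Mann-Whitney count U of a lower ordinal group against a higher one.

    ``U = sum_{a in y1} sum_{b in y2} phi(a, b)`` with ties counted as
    one half.  Both inputs must be sorted ascending.  Computed by a
    single simultaneous merge scan: two pointers advance along the two
    vectors (by runs where values tie), so the work is at most
    ``len(y1) + len(y2)`` steps.  Accumulation is an integer in doubled
    units, so the result is exact.
    """
    a = list(y1)
    b = list(y2)
    n1 = len(a)
    n2 = len(b)
    if n1 == 0 or n2 == 0:
        return 0.0
    u2 = 0
    i = 0
    j = 0
    steps = 0
    while i < n1 and j < n2:
        steps += 1
        ai = a[i]
        bj = b[j]
        if ai < bj:
            # everything remaining in y2 exceeds a[i]
            u2 += 2 * (n2 - j)
            i += 1
        elif ai > bj:
            j += 1
        else:
            # tie: consume the full run of this value in both vectors
            ri = i + 1
            while ri < n1 and a[ri] == ai:
                ri += 1
                steps += 1
            rj = j + 1
            while rj < n2 and b[rj] == bj:
                rj += 1
                steps += 1
            n_tied = rj - j
            u2 += (ri - i) * (2 * (n2 - rj) + n_tied)
            i = ri
            j = rj
    if counter is not None:
        counter.merge_steps += steps
    return u2 / 2.0


def jt_statistic(g: GroupedTrait, counter: Optional[OpCounter] = None) -> float:
    """J = sum of Mann-Whitney counts over all ordered level pairs."""
    groups = [grp for grp in g.groups if len(grp)]
    t = len(groups)
    j2 = 0.0
    for k in range(t - 1):
        for l in range(k + 1, t):
            j2 += mann_whitney_count(groups[k], groups[l], counter=counter)
    return j2


def tie_block_sizes(values) -> np.ndarray:
    """Sizes of maximal blocks of exactly equal values in a pooled vector."""
    v = _as_float_array(values)
    if v.size == 0:
        return np.empty(0, dtype=np.int64)
    _, counts = np.unique(v, return_counts=True)
    return counts.astype(np.int64)


def null_moments(group_sizes, tie_sizes) -> NullMoments:
    """Permutation-null mean and tie-corrected variance of J.

    E[J] = (n^2 - sum n_k^2) / 4.

    Var[J] = A/72 + B/(36 n(n-1)(n-2)) + C/(8 n(n-1)) with

        A = n(n-1)(2n+5) - sum_k n_k(n_k-1)(2n_k+5)
                         - sum_j t_j(t_j-1)(2t_j+5)
        B = [sum_k n_k(n_k-1)(n_k-2)] * [sum_j t_j(t_j-1)(t_j-2)]
        C = [sum_k n_k(n_k-1)] * [sum_j t_j(t_j-1)]

    where n_k are group sizes and t_j tie-block sizes of the pooled
    trait values.  The B and C terms are zero when their denominators
    vanish (n <= 2).  When every t_j = 1 this reduces to the classical
    no-ties form [n^2(2n+3) - sum n_k^2 (2n_k+3)] / 72.  Tiny negative
    round-off is clamped to zero.
    """
    nk = np.asarray(group_sizes, dtype=np.int64)
    tj = np.asarray(tie_sizes, dtype=np.int64)
    n = int(nk.sum())
    if tj.size and int(tj.sum()) != n:
        raise ValueError("tie_sizes must sum to the total sample size")
    # exact integer arithmetic via python ints
    nks = [int(x) for x in nk]
    tjs = [int(x) for x in tj]
    e0 = (n * n - sum(x * x for x in nks)) / 4.0
    a_term = (
        n * (n - 1) * (2 * n + 5)
        - sum(x * (x - 1) * (2 * x + 5) for x in nks)
        - sum(x * (x - 1) * (2 * x + 5) for x in tjs)
    )
    var0 = a_term / 72.0
    if n > 2:
        b_num = sum(x * (x - 1) * (x - 2) for x in nks) * sum(
            x * (x - 1) * (x - 2) for x in tjs
        )
        var0 += b_num / (36.0 * n * (n - 1) * (n - 2))
    if n > 1:
        c_num = sum(x * (x - 1) for x in nks) * sum(x * (x - 1) for x in tjs)
        var0 += c_num / (8.0 * n * (n - 1))
    if var0 < 0.0:
        var0 = 0.0
    return NullMoments(
        e0=e0, var0=var0, n=n, group_sizes=nk, tie_sizes=tj
    )


def outcome_from_grouped(
    g: GroupedTrait,
    sided: str = "two",
    counter: Optional[OpCounter] = None,
) -> JTOutcome:
    """Standardized JT test from a pre-grouped trait (shared with the scan)."""
    sizes = g.group_sizes
    nonempty = int((sizes > 0).sum())
    if g.n_total < 2 or nonempty < 2:
        return JTOutcome(
            j_stat=0.0, z=None, p_two_sided=None, moments=None,
            status=Status.DEGENERATE_GROUPS, n_used=g.n_total,
        )
    j = jt_statistic(g, counter=counter)
    pooled = g.pooled_sorted()
    mom = null_moments(sizes[sizes > 0], tie_block_sizes(pooled))
    if mom.var0 <= 0.0:
        return JTOutcome(
            j_stat=j, z=None, p_two_sided=None, moments=mom,
            status=Status.ZERO_VARIANCE, n_used=g.n_total,
        )
    z = (j - mom.e0) / math.sqrt(mom.var0)
    if sided == "two":
        p = 2.0 * norm.sf(abs(z))
    elif sided == "one":
        p = float(norm.sf(z))
    else:
        raise ValueError(f"sided must be 'two' or 'one', got {sided!r}")
    p = min(float(p), 1.0)
    return JTOutcome(
        j_stat=j, z=float(z), p_two_sided=p, moments=mom,
        status=Status.OK, n_used=g.n_total,
    )


def jt_test(
    values,
    labels,
    sided: str = "two",
    counter: Optional[OpCounter] = None,
) -> JTOutcome:
    """End-to-end JT test for one feature-trait pair.

    Groups ``values`` by ordinal ``labels`` (dropping missing entries),
    computes J by the merge-scan kernel, standardizes by the tie-corrected
    null moments and refers Z to the standard normal (no continuity
    correction; two-sided by default).  Degenerate inputs come back as
    flagged outcomes, never exceptions, so batch scans proceed.
    """
    g = sort_into_groups(values, labels)
    return outcome_from_grouped(g, sided=sided, counter=counter)


def brute_force_jt(values, labels, counter: Optional[OpCounter] = None) -> float:
    """Naive O(n^2) JT statistic by exhaustive pairwise comparison.

    Test oracle and complexity-probe comparator; exact (doubled-unit
    integer accumulation).  The operation counter records one comparison
    per cross-group pair, n_k * n_l for each ordered level pair.
    """
    g = sort_into_groups(values, labels)
    groups = [np.asarray(grp, dtype=float) for grp in g.groups if len(grp)]
    t = len(groups)
    j2 = 0
    for k in range(t - 1):
        for l in range(k + 1, t):
            a = groups[k][:, None]
            b = groups[l][None, :]
            j2 += 2 * int(np.sum(a < b)) + int(np.sum(a == b))
            if counter is not None:
                counter.pair_comparisons += groups[k].size * groups[l].size
    return j2 / 2.0


def _assignments(indices: tuple, sizes: Sequence[int]):
    """Yield all distinct assignments of index positions into groups."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for head in itertools.combinations(indices, sizes[0]):
        chosen = set(head)
        rest = tuple(x for x in indices if x not in chosen)
        for tail in _assignments(rest, sizes[1:]):
            yield (head,) + tail


def permutation_null_exhaustive(values, group_sizes) -> np.ndarray:
    """Exact null distribution of J by exhaustive enumeration (n <= 10).

    Enumerates every distinct assignment of the pooled values to groups
    of the given sizes (all equally likely under the permutation null)
    and returns the array of J values — the oracle against which the
    closed-form null moments are checked, ties included.
    """
    v = _as_float_array(values)
    sizes = [int(s) for s in group_sizes]
    n = int(v.size)
    if sum(sizes) != n:
        raise ValueError("group sizes must sum to the number of values")
    if n > 10:
        raise ValueError("exhaustive enumeration limited to n <= 10")
    labels = np.empty(n, dtype=np.int64)
    out = []
    for assign in _assignments(tuple(range(n)), sizes):
        for k, idx in enumerate(assign):
            labels[list(idx)] = k
        out.append(brute_force_jt(v, labels))
    return np.asarray(out)
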