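"""Count-family selection, GLM post-hoc letters, rank tests, proportions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shootzones.compare import (
    compact_letter_display, compare_lateral_counts,
    compare_lateral_proportions, compare_node_numbers, select_count_family,
)
from shootzones.errors import DataError


# ---------------------------------------------------------------------- #
# family selection
# ---------------------------------------------------------------------- #

def test_family_selection_poisson_draws():
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        if select_count_family(rng.poisson(5, 300)).family == "poisson":
            wins += 1
    assert wins >= 9


def test_family_selection_overdispersed_draws():
    rng = np.random.default_rng(0)
    # variance ~ 5x mean
    counts = rng.negative_binomial(2, 2 / 10, size=300)
    assert select_count_family(counts).family == "negative-binomial"


def test_family_selection_constant_counts_defined():
    sel = select_count_family([4] * 30)
    assert sel.family == "poisson" and "constant" in sel.note


# ---------------------------------------------------------------------- #
# node numbers: GLM + compact letters
# ---------------------------------------------------------------------- #

def test_identical_groups_share_one_letter():
    g = np.array([5, 6, 7, 8, 9, 10] * 5)
    res = compare_node_numbers({"a": g, "b": g.copy(), "c": g.copy()})
    assert len(set(res.letters.values())) == 1
    assert all(p.code == "ns" for p in res.pairwise)


def test_published_node_means_fully_separated():
    # mean node numbers 8 / 20 / 35 per shoot at n = 50
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        groups = {
            "short": rng.poisson(8, 50), "medium": rng.poisson(20, 50),
            "long": rng.poisson(35, 50),
        }
        res = compare_node_numbers(groups)
        letters = set(res.letters.values())
        hits += letters == {"a", "b", "c"}
    assert hits >= 9


def test_two_groups_single_contrast():
    rng = np.random.default_rng(1)
    res = compare_node_numbers({"a": rng.poisson(8, 40), "b": rng.poisson(20, 40)})
    assert len(res.pairwise) == 1 and res.pairwise[0].pvalue < 0.001
    assert res.letters["a"] != res.letters["b"]


def test_group_too_small_rejected():
    with pytest.raises(DataError):
        compare_node_numbers({"a": [1, 2], "b": [3, 4, 5]})


@settings(max_examples=60, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 4)), max_size=6))
def test_letter_display_consistency(pairs):
    groups = list("abcde")
    sig = [(groups[i], groups[j]) for i, j in pairs if i != j]
    letters = compact_letter_display(groups, sig)
    for a, b in sig:
        assert not set(letters[a]) & set(letters[b])
    sig_set = {frozenset(p) for p in sig}
    for a in groups:
        for b in groups:
            if a < b and frozenset((a, b)) not in sig_set:
                assert set(letters[a]) & set(letters[b])


# ---------------------------------------------------------------------- #
# rank-based lateral-count comparisons
# ---------------------------------------------------------------------- #

def test_rank_tests_identical_groups_null():
    g = [1, 2, 3, 4, 5]
    res = compare_lateral_counts({"a": g, "b": list(g), "c": list(g)})
    assert res.test == "kruskal-wallis" and res.code == "ns"


def test_rank_tests_all_tied_defined():
    res = compare_lateral_counts({"a": [2, 2, 2], "b": [2, 2, 2], "c": [2, 2, 2]})
    assert res.pvalue == 1.0 and res.posthoc == []


def test_rank_tests_shifted_distributions_detected():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        base = rng.poisson(5, 40)
        res = compare_lateral_counts({
            "a": base, "b": rng.poisson(5, 40) + 3, "c": rng.poisson(5, 40)})
        hits += res.pvalue < 0.05
        if res.pvalue < 0.05:
            assert res.posthoc  # Dunn post hoc runs on a significant omnibus
    assert hits >= 9


def test_two_group_route_is_mann_whitney():
    rng = np.random.default_rng(0)
    res = compare_lateral_counts({"a": rng.poisson(5, 30), "b": rng.poisson(9, 30)})
    assert res.test == "mann-whitney" and res.pvalue < 0.05


# ---------------------------------------------------------------------- #
# lateral-type proportions
# ---------------------------------------------------------------------- #

def test_proportions_proportional_table_null():
    res = compare_lateral_proportions([[10, 20, 30], [20, 40, 60]])
    assert res.test == "chi-square" and res.pvalue > 0.9 and res.posthoc == []


def test_proportions_diagonal_table_significant():
    res = compare_lateral_proportions([[10, 0], [0, 10]])
    assert res.pvalue < 0.001


def test_proportions_sparse_table_routes_to_fisher():
    res = compare_lateral_proportions([[3, 0, 1, 0, 2], [1, 2, 0, 1, 0]])
    assert res.test == "fisher" and res.flagged_small
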