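"""Zone extraction, occurrence tables, zone-length and lateral-type tests."""

import numpy as np
import pytest

from helpers import enum_fisher_p
from shootzones.errors import DataError
from shootzones.hsmm import DecodedPath
from shootzones.occupancy import OccupancyDist
from shootzones.zones import (
    compare_lateral_distributions, compare_zone_lengths,
    correlate_zone_vs_total, extract_zones, occurrence_probabilities,
)


def path(states, symbols=None, shoot_id="s"):
    states = np.asarray(states)
    symbols = np.zeros_like(states) if symbols is None else np.asarray(symbols)
    return DecodedPath(symbols, states, 0.0, shoot_id)


# ---------------------------------------------------------------------- #
# zones
# ---------------------------------------------------------------------- #

@pytest.mark.parametrize("states,expected", [
    ([0, 0, 0, 1, 1, 2], [(0, 0, 3), (1, 3, 5), (2, 5, 6)]),
    ([0, 0, 2, 2], [(0, 0, 2), (2, 2, 4)]),
    ([1], [(1, 0, 1)]),
])
def test_extract_zones(states, expected):
    prof = extract_zones(path(states))
    assert [(z.state, z.start, z.end) for z in prof.zones] == expected
    assert sum(z.length for z in prof.zones) == len(states)


def test_extract_zones_rejects_decreasing():
    with pytest.raises(DataError):
        extract_zones(path([1, 0]))


def test_occurrence_probabilities_fractions():
    profs = [extract_zones(path([0, 0, 1])) for _ in range(26)]
    profs += [extract_zones(path([0, 0])) for _ in range(74)]
    tab = occurrence_probabilities({"g": profs}, [0, 1, 2], ["S0", "S1", "S2"])
    assert tab.loc["g", "S0"] == 1.0
    assert tab.loc["g", "S1"] == pytest.approx(0.26)
    assert tab.loc["g", "S2"] == 0.0
    assert tab.loc["g", "n"] == 100


# ---------------------------------------------------------------------- #
# zone-length comparison
# ---------------------------------------------------------------------- #

def test_zone_lengths_identical_groups_not_significant():
    g = [3, 5, 7, 9, 4, 6, 8, 5, 6, 7]
    res = compare_zone_lengths(g, list(g))
    assert res.performed and res.pvalue > 0.05 and res.code == "ns"


def test_zone_lengths_no_test_below_three():
    res = compare_zone_lengths([4, 5], [3, 4, 5, 6])
    assert not res.performed and res.pvalue is None


def test_zone_lengths_power_published_means():
    # medium- vs short-GD diffuse floral zone lengths: 13.4 vs 3.9 nodes
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        a = OccupancyDist.shifted_negbin(13.4, 2.0).sample(rng, 50)
        b = OccupancyDist.shifted_negbin(3.9, 2.0).sample(rng, 50)
        res = compare_zone_lengths(a, b)
        hits += res.code in ("*", "**")
    assert hits >= 9


# ---------------------------------------------------------------------- #
# Fisher's exact test
# ---------------------------------------------------------------------- #

def test_fisher_2x2_known_value():
    res = compare_lateral_distributions([[3, 1], [1, 3]])
    assert res.pvalue == pytest.approx(0.485714, abs=1e-5)


def test_fisher_proportional_rows_p_one():
    res = compare_lateral_distributions([[10, 20, 30], [1, 2, 3]])
    assert res.pvalue == pytest.approx(1.0, abs=1e-9)


def test_fisher_enumeration_matches_independent_oracle(rng):
    # all 2x3 tables with total <= 15 drawn at random
    for _ in range(25):
        t = rng.integers(0, 4, size=(2, 3))
        if t.sum() == 0 or t.sum() > 15:
            continue
        if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
            continue
        got = compare_lateral_distributions(t).pvalue
        want = enum_fisher_p(t)
        assert got == pytest.approx(want, abs=1e-9)


def test_fisher_monte_carlo_deterministic():
    t = np.array([[120, 80, 40], [60, 100, 90]])  # total > 200 -> MC route
    r1 = compare_lateral_distributions(t)
    r2 = compare_lateral_distributions(t)
    assert r1.monte_carlo and r1.pvalue == r2.pvalue
    assert r1.pvalue < 0.01  # strong association by construction


# ---------------------------------------------------------------------- #
# correlations
# ---------------------------------------------------------------------- #

def test_correlation_perfect_linear():
    profs = [extract_zones(path([0] * a + [1] * (2 * a)))
             for a in (2, 3, 4, 5)]
    res = correlate_zone_vs_total(profs, 1)
    assert res.r == pytest.approx(1.0) and res.r_squared == pytest.approx(1.0)


def test_correlation_constant_zone_undefined():
    profs = [extract_zones(path([0] * a + [1] * 3)) for a in (2, 3, 4)]
    res = correlate_zone_vs_total(profs, 1)
    assert res.r is None and "variance" in res.note


def test_correlation_matches_analytic_r_squared(rng):
    # floral zone = 0.6 * base + noise; total = base + floral
    base = rng.normal(20, 5, size=300).clip(5)
    noise = rng.normal(0, 2, size=300)
    floral = np.maximum(np.round(0.6 * base + noise), 1).astype(int)
    profs = []
    for b, f in zip(np.round(base).astype(int), floral):
        profs.append(extract_zones(path([0] * b + [1] * f)))
    res = correlate_zone_vs_total(profs, 1)
    # analytic: corr^2 between f = 0.6 b + e and t = b + f
    var_b, var_e = 25.0, 4.0
    cov_ft = 0.6 * var_b + 0.6 * 0.6 * var_b + var_e
    var_f = 0.36 * var_b + var_e
    var_t = var_b + var_f + 2 * 0.6 * var_b
    r2 = cov_ft ** 2 / (var_f * var_t)
    assert res.r_squared == pytest.approx(r2, abs=0.15)
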