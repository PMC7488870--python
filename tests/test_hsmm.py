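"""Likelihood, Viterbi, simulation and EM for the constrained chains.

The dynamic-programming recursions are checked against brute-force
enumeration over every feasible segmentation (independent oracle) on toy
specs with up to 3 transient states and sequences of length up to 8.
"""

import numpy as np
import pytest

from helpers import enum_loglik, enum_viterbi, floral_state, random_toy_spec
from shootzones.errors import DataError
from shootzones.hsmm import (
    EmissionDist, EMSettings, HiddenSemiMarkovModel, HSMMSpec, fit_em,
    log_likelihood, monocyclic_template, simulate, viterbi_decode,
)
from shootzones.occupancy import OccupancyDist
from shootzones.synthetic import monocyclic_spec


def single_state_spec(occ, emission=None):
    return HSMMSpec(
        initial=np.array([1.0]),
        transitions=np.array([[0.0, 1.0]]),
        occupancies=[occ],
        emissions=[emission or EmissionDist.delta(0)],
        support_max=150,
    )


# ---------------------------------------------------------------------- #
# likelihood
# ---------------------------------------------------------------------- #

def test_forced_path_likelihood():
    spec = single_state_spec(OccupancyDist.point(4))
    assert log_likelihood(spec, np.zeros(4, dtype=int)) == pytest.approx(0.0, abs=1e-12)
    assert log_likelihood(spec, np.zeros(3, dtype=int)) == -np.inf


def test_symbol_outside_alphabet_raises():
    spec = single_state_spec(OccupancyDist.point(2))
    with pytest.raises(DataError):
        log_likelihood(spec, np.array([0, 9]))


def test_likelihood_matches_enumeration_oracle(rng):
    for trial in range(10):
        spec = random_toy_spec(rng)
        for T in (1, 3, 5, 8):
            seq = rng.integers(0, 3, size=T)
            got = log_likelihood(spec, seq)
            want = enum_loglik(spec, seq)
            if want == -np.inf:
                assert got == -np.inf
            else:
                assert got == pytest.approx(want, abs=1e-10)


def test_single_state_geometric_matches_closed_form():
    # geometric occupancy (shifted NB with shape 1) + categorical emissions
    # degenerate to an i.i.d. categorical model with a stopping rule
    p_stop = 0.35
    emis = EmissionDist(np.array([0.5, 0.3, 0.2, 0.0, 0.0, 0.0]))
    spec = single_state_spec(
        OccupancyDist("shifted-negbin", {"r": 1.0, "p": p_stop}), emis)
    spec.support_max = 500
    rng = np.random.default_rng(1)
    for T in (1, 4, 9):
        seq = rng.integers(0, 3, size=T)
        closed = (T - 1) * np.log(1 - p_stop) + np.log(p_stop) \
            + np.sum(np.log(emis.probs[seq]))
        assert log_likelihood(spec, seq) == pytest.approx(closed, abs=1e-12)


# ---------------------------------------------------------------------- #
# Viterbi
# ---------------------------------------------------------------------- #

def test_viterbi_matches_enumeration_oracle(rng):
    for trial in range(10):
        spec = random_toy_spec(rng, n_states=3)
        for T in (2, 5, 8):
            seq = rng.integers(0, 3, size=T)
            want_lp, want_path = enum_viterbi(spec, seq)
            if want_path is None:
                continue
            got = viterbi_decode(spec, seq)
            assert got.log_joint == pytest.approx(want_lp, abs=1e-9)


def test_viterbi_deterministic_chain():
    spec = HSMMSpec(
        initial=np.array([1.0, 0.0]),
        transitions=np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]),
        occupancies=[OccupancyDist.point(2), OccupancyDist.point(3)],
        emissions=[EmissionDist.delta(0), EmissionDist.delta(2)],
    )
    path = viterbi_decode(spec, np.array([0, 0, 2, 2, 2]))
    assert np.array_equal(path.states, [0, 0, 1, 1, 1])


def test_viterbi_tie_breaks_to_lowest_state():
    # two states with identical emissions/occupancies and equal entry
    # probability: the decoded path must use the lower state index
    spec = HSMMSpec(
        initial=np.array([0.5, 0.5]),
        transitions=np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]]),
        occupancies=[OccupancyDist.point(3), OccupancyDist.point(3)],
        emissions=[EmissionDist.delta(0), EmissionDist.delta(0)],
    )
    path = viterbi_decode(spec, np.zeros(3, dtype=int))
    assert np.array_equal(path.states, [0, 0, 0])


def test_viterbi_error_on_impossible_sequence():
    spec = single_state_spec(OccupancyDist.point(3))
    with pytest.raises(DataError, match="node 1"):
        viterbi_decode(spec, np.array([0, 5, 0]))


def test_decoded_paths_partition_and_bound(rng):
    spec = monocyclic_spec(0.4, 0.3, both=0.1)
    seqs, _ = simulate(spec, 50, seed=rng)
    for seq in seqs:
        path = viterbi_decode(spec, seq)
        assert len(path.states) == len(seq)
        assert np.all(np.diff(path.states) >= 0)
        assert path.log_joint <= log_likelihood(spec, seq) + 1e-9


# ---------------------------------------------------------------------- #
# simulation
# ---------------------------------------------------------------------- #

def test_simulate_deterministic_and_visit_fraction():
    spec = monocyclic_spec(0.26, 0.09)
    seqs1, paths1 = simulate(spec, 200, seed=42)
    seqs2, paths2 = simulate(spec, 200, seed=42)
    assert all(np.array_equal(a, b) for a, b in zip(seqs1, seqs2))
    _, paths = simulate(spec, 10_000, seed=7)
    frac = np.mean([np.any(p == 1) for p in paths])
    se = np.sqrt(0.26 * 0.74 / 10_000)
    assert abs(frac - 0.26) < 3 * se


def test_simulate_point_mass_durations():
    spec = single_state_spec(OccupancyDist.point(5))
    seqs, paths = simulate(spec, 10, seed=0)
    assert all(len(s) == 5 for s in seqs)


# ---------------------------------------------------------------------- #
# EM estimation
# ---------------------------------------------------------------------- #

def test_em_loglik_monotone(rng):
    spec = monocyclic_spec(0.4, 0.2)
    seqs, _ = simulate(spec, 60, seed=rng)
    res = fit_em(seqs, monocyclic_template(), n_restarts=2, seed=3, max_iter=60)
    trace = np.asarray(res.loglik_trace)
    assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))


def test_em_forced_latent_structure_preserved(rng):
    lengths = rng.poisson(5, size=40) + 1
    seqs = [np.zeros(n, dtype=int) for n in lengths]
    template = single_state_spec(OccupancyDist.shifted_poisson(3.0))
    res = fit_em(seqs, template, n_restarts=1, seed=0)
    assert res.spec.emissions[0].probs[0] == 1.0
    assert res.spec.occupancies[0].mean() == pytest.approx(lengths.mean(), rel=0.05)


def test_em_recovers_entry_probability(rng):
    truth = monocyclic_spec(0.26, 0.09)
    seqs, _ = simulate(truth, 500, seed=11)
    res = fit_em(seqs, monocyclic_template(9.0), n_restarts=6, seed=2)
    fl = floral_state(res.spec)
    assert res.spec.transitions[0, fl] == pytest.approx(0.26, abs=0.05)


def test_em_rejects_impossible_sequences():
    template = monocyclic_template()  # no state can emit the scar symbol
    with pytest.raises(DataError):
        fit_em([np.array([0, 0, 5, 5])], template, n_restarts=1, seed=0)


def test_spec_serialization_roundtrip(tmp_path, rng):
    truth = monocyclic_spec(0.26, 0.09)
    seqs, _ = simulate(truth, 80, seed=rng)
    res = fit_em(seqs, monocyclic_template(9.0), n_restarts=2, seed=0)
    p = tmp_path / "model.yaml"
    res.spec.save(p)
    back = HSMMSpec.from_dict(res.spec.to_dict())
    loaded = HSMMSpec.load(p)
    for other in (back, loaded):
        np.testing.assert_allclose(other.transitions, res.spec.transitions, rtol=1e-10)
        for a, b in zip(other.occupancies, res.spec.occupancies):
            assert a.family == b.family
            for k, v in b.params.items():
                assert a.params[k] == pytest.approx(v, rel=1e-11)
        for a, b in zip(other.emissions, res.spec.emissions):
            np.testing.assert_allclose(a.probs, b.probs, rtol=1e-10)


def test_results_summary_mentions_states(rng):
    truth = monocyclic_spec(0.3, 0.1)
    seqs, _ = simulate(truth, 40, seed=rng)
    res = HiddenSemiMarkovModel(seqs, monocyclic_template(9.0)).fit(
        EMSettings(n_restarts=1, seed=0, max_iter=50))
    text = res.summary()
    assert "S0" in text and "BIC" in text and "transitions" in text
    assert np.isfinite(res.bic) and np.isfinite(res.loglik)
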