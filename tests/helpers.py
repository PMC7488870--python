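"""Shared independent oracles for the test suite.

The brute-force routines enumerate every (state subset, segmentation) pair
explicitly and therefore stay independent of the dynamic-programming
recursions they check.
"""

import itertools

import numpy as np

from shootzones.hsmm import EmissionDist, HSMMSpec
from shootzones.occupancy import OccupancyDist


def random_toy_spec(rng, n_states=None, n_symbols=3, support_max=30) -> HSMMSpec:
    """Random valid left-to-right spec with <= 3 transient states."""
    S = int(n_states or rng.integers(1, 4))
    trans = np.zeros((S, S + 1))
    for i in range(S):
        cols = list(range(i + 1, S)) + [S]
        trans[i, cols] = rng.dirichlet(np.ones(len(cols)))
    init = rng.dirichlet(np.ones(S))
    occ = [OccupancyDist.shifted_poisson(1 + rng.uniform(0.2, 3)) for _ in range(S)]
    emis = []
    for _ in range(S):
        p = np.zeros(6)
        p[:n_symbols] = rng.dirichlet(np.ones(n_symbols))
        emis.append(EmissionDist(p))
    return HSMMSpec(init, trans, occ, emis, support_max=support_max)


def _segmentations(spec, seq):
    """Yield (log prob, per-node states) for every feasible segmentation."""
    T = len(seq)
    S = spec.n_states
    logD = np.vstack([o.log_pmf_vector(spec.support_max) for o in spec.occupancies])
    for k in range(1, T + 1):
        for states in itertools.combinations(range(S), k):
            pp = spec.initial[states[0]]
            for a, b in zip(states, states[1:]):
                pp *= spec.transitions[a, b]
            pp *= spec.transitions[states[-1], S]
            if pp == 0:
                continue
            for cuts in itertools.combinations(range(1, T), k - 1):
                bounds = (0,) + cuts + (T,)
                p = pp
                for idx, j in enumerate(states):
                    d = bounds[idx + 1] - bounds[idx]
                    p *= np.exp(logD[j, d - 1])
                    for u in range(bounds[idx], bounds[idx + 1]):
                        p *= spec.emissions[j].probs[seq[u]]
                if p > 0:
                    path = np.concatenate([
                        np.full(bounds[i + 1] - bounds[i], states[i])
                        for i in range(k)
                    ])
                    yield np.log(p), path


def enum_loglik(spec, seq) -> float:
    total = 0.0
    for lp, _ in _segmentations(spec, seq):
        total += np.exp(lp)
    return np.log(total) if total > 0 else -np.inf


def enum_viterbi(spec, seq):
    best_lp, best_path = -np.inf, None
    for lp, path in _segmentations(spec, seq):
        if lp > best_lp + 1e-12:
            best_lp, best_path = lp, path
    return best_lp, best_path


def enum_fisher_p(table) -> float:
    """Independent Fisher p: enumerate cell-by-cell over the full product
    space, keeping tables with matching margins."""
    from scipy.special import gammaln

    t = np.asarray(table, dtype=np.int64)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    N = int(t.sum())
    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(N + 1)

    def logp(tab):
        return const - gammaln(np.asarray(tab) + 1.0).sum()

    lp_obs = logp(t)
    shape = t.shape
    ranges = [range(min(rows[i // shape[1]], cols[i % shape[1]]) + 1)
              for i in range(t.size)]
    total = 0.0
    for cells in itertools.product(*ranges):
        tab = np.asarray(cells).reshape(shape)
        if np.array_equal(tab.sum(axis=1), rows) and np.array_equal(tab.sum(axis=0), cols):
            lp = logp(tab)
            if lp <= lp_obs + 1e-7:
                total += np.exp(lp)
    return min(total, 1.0)


def floral_state(spec, candidates=(1, 2)) -> int:
    """Identify the diffuse floral zone among free states by bourse mass."""
    mass = {j: spec.emissions[j].probs[3] + spec.emissions[j].probs[4]
            for j in candidates}
    return max(mass, key=mass.get)
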