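"""Inner recursions for explicit-duration left-to-right semi-Markov chains.

All kernels work in log space on pre-computed tables:

* ``logpi``  (S,)       initial log probabilities over transient states
* ``logAt`` (S, S)      transient->transient transition log probs
* ``logAe`` (S,)        transient->end log probs
* ``logD``  (S, Dmax)   occupancy log pmf, entry d-1 holds duration d
* ``logB``  (S, T)      per-node emission log prob of the observed symbol

``alpha[j, t]`` is the log probability of the first ``t`` symbols jointly
with "the zone of state j ends at node t"; ``in_[j, t]`` the log probability
of entering state j at node t.  Because every state is transient and
transitions are strictly left-to-right, each state appears in at most one
zone and the recursion over zone end-times is exact.
"""

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def _lse(buf, n):
    m = NEG_INF
    for i in range(n):
        if buf[i] > m:
            m = buf[i]
    if m == NEG_INF:
        return NEG_INF
    s = 0.0
    for i in range(n):
        s += np.exp(buf[i] - m)
    return m + np.log(s)


@njit(cache=True)
def forward(logpi, logAt, logAe, logD, logB):
    """Forward pass; returns (alpha, in_, cum, loglik)."""
    S, T = logB.shape
    Dmax = logD.shape[1]
    cum = np.zeros((S, T + 1))
    for j in range(S):
        for t in range(T):
            cum[j, t + 1] = cum[j, t] + logB[j, t]
    alpha = np.full((S, T + 1), NEG_INF)
    in_ = np.full((S, T + 1), NEG_INF)
    for j in range(S):
        in_[j, 0] = logpi[j]
    buf = np.empty(max(Dmax, S))
    for t in range(1, T + 1):
        nd = min(t, Dmax)
        for j in range(S):
            for d in range(1, nd + 1):
                buf[d - 1] = logD[j, d - 1] + cum[j, t] - cum[j, t - d] + in_[j, t - d]
            alpha[j, t] = _lse(buf, nd)
        if t < T:
            for j in range(S):
                for i in range(S):
                    buf[i] = alpha[i, t] + logAt[i, j]
                in_[j, t] = _lse(buf, S)
    for j in range(S):
        buf[j] = alpha[j, T] + logAe[j]
    ll = _lse(buf, S)
    return alpha, in_, cum, ll


@njit(cache=True)
def estep(logpi, logAt, logAe, logD, logB,
          init_post, trans_post, end_post, dur_post, gamma):
    """One E-step for a single sequence; accumulates expected counts.

    ``init_post`` (S,), ``trans_post`` (S, S), ``end_post`` (S,),
    ``dur_post`` (S, Dmax) and ``gamma`` (S, T) are accumulated in place
    (gamma must be zeroed by the caller; the others accumulate across
    sequences).  Returns the sequence log-likelihood.
    """
    S, T = logB.shape
    Dmax = logD.shape[1]
    alpha, in_, cum, ll = forward(logpi, logAt, logAe, logD, logB)
    if ll == NEG_INF:
        return ll

    beta = np.full((S, T + 1), NEG_INF)
    inb = np.full((S, T + 1), NEG_INF)
    for j in range(S):
        beta[j, T] = logAe[j]
    buf = np.empty(max(Dmax, S))
    for t in range(T - 1, -1, -1):
        for j in range(S):
            nd = min(T - t, Dmax)
            for d in range(1, nd + 1):
                buf[d - 1] = logD[j, d - 1] + cum[j, t + d] - cum[j, t] + beta[j, t + d]
            inb[j, t] = _lse(buf, nd)
        for i in range(S):
            for j in range(S):
                buf[j] = logAt[i, j] + inb[j, t]
            beta[i, t] = _lse(buf, S)

    for j in range(S):
        v = logpi[j] + inb[j, 0] - ll
        if v > -700.0:
            init_post[j] += np.exp(v)
    for t in range(1, T):
        for i in range(S):
            if alpha[i, t] == NEG_INF:
                continue
            for j in range(S):
                v = alpha[i, t] + logAt[i, j] + inb[j, t] - ll
                if v > -700.0:
                    trans_post[i, j] += np.exp(v)
    for i in range(S):
        v = alpha[i, T] + logAe[i] - ll
        if v > -700.0:
            end_post[i] += np.exp(v)

    # segment posteriors -> duration counts and per-node state posteriors
    for j in range(S):
        for s in range(T):
            if in_[j, s] == NEG_INF:
                continue
            nd = min(T - s, Dmax)
            for d in range(1, nd + 1):
                v = in_[j, s] + logD[j, d - 1] + cum[j, s + d] - cum[j, s] \
                    + beta[j, s + d] - ll
                if v > -700.0:
                    w = np.exp(v)
                    dur_post[j, d - 1] += w
                    for u in range(s, s + d):
                        gamma[j, u] += w
    return ll


@njit(cache=True)
def viterbi(logpi, logAt, logAe, logD, logB):
    """Most probable segmentation; returns (states, log_joint).

    Ties are broken toward the earliest predecessor (sequence start first,
    then the lowest state index) and then the shorter zone duration, so the
    restored path prefers low state indices and short initial zones.
    """
    S, T = logB.shape
    Dmax = logD.shape[1]
    cum = np.zeros((S, T + 1))
    for j in range(S):
        for t in range(T):
            cum[j, t + 1] = cum[j, t] + logB[j, t]
    score = np.full((S, T + 1), NEG_INF)     # best path with zone of j ending at t
    bp_prev = np.full((S, T + 1), -2, dtype=np.int64)  # -1 = sequence start
    bp_dur = np.zeros((S, T + 1), dtype=np.int64)
    # entry[j, s]: best score entering state j at node s (paired with entry_prev)
    entry = np.full((S, T + 1), NEG_INF)
    entry_prev = np.full((S, T + 1), -2, dtype=np.int64)
    for j in range(S):
        entry[j, 0] = logpi[j]
        entry_prev[j, 0] = -1
    for t in range(1, T + 1):
        nd = min(t, Dmax)
        for j in range(S):
            best = NEG_INF
            bprev = -2
            bdur = 0
            # candidate order: earlier entry (handled via entry_prev), shorter d
            for d in range(1, nd + 1):
                s = t - d
                if entry[j, s] == NEG_INF:
                    continue
                v = entry[j, s] + logD[j, d - 1] + cum[j, t] - cum[j, s]
                if v > best:
                    best = v
                    bprev = entry_prev[j, s]
                    bdur = d
            score[j, t] = best
            bp_prev[j, t] = bprev
            bp_dur[j, t] = bdur
        if t < T:
            for j in range(S):
                best = NEG_INF
                bprev = -2
                for i in range(S):
                    v = score[i, t] + logAt[i, j]
                    if v > best:
                        best = v
                        bprev = i
                entry[j, t] = best
                entry_prev[j, t] = bprev
    best = NEG_INF
    bj = -1
    for j in range(S):
        v = score[j, T] + logAe[j]
        if v > best:
            best = v
            bj = j
    states = np.empty(T, dtype=np.int64)
    if bj < 0:
        return states[:0], NEG_INF
    t = T
    j = bj
    while t > 0:
        d = bp_dur[j, t]
        prev = bp_prev[j, t]
        for u in range(t - d, t):
            states[u] = j
        t -= d
        if prev == -1:
            break
        j = prev
    return states, best
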