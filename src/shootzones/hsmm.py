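"""Constrained hidden semi-Markov chains over categorical bud-fate sequences.

The chain is left-to-right and transient: states are ordered, a state can
never be revisited, and an absorbing non-emitting end state terminates the
sequence.  Each transient state (a branching *zone*) carries

* an explicit occupancy distribution — the zone length in nodes
  (:class:`~shootzones.occupancy.OccupancyDist`), and
* a categorical observation distribution over the six bud-fate symbols
  (0 latent, 1 short vegetative, 2 long vegetative, 3 bourse with short
  bourse shoot, 4 bourse with long bourse shoot, 5 bud scar).

Structural constraints (forced-latent basal zones, the forced bud-scar
cessation zone of bicyclic shoots) are expressed through emission masks and
transition zero-patterns, and are preserved exactly through EM.

The statsmodels-flavoured surface is :class:`HiddenSemiMarkovModel` /
:class:`HSMMResults`; the functional helpers ``log_likelihood``,
``viterbi_decode``, ``fit_em`` and ``simulate`` delegate to it.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import yaml

from . import _recursions
from .errors import ConfigError, DataError
from .occupancy import OccupancyDist, fit_family

logger = logging.getLogger("shootzones")

N_SYMBOLS = 6
SYMBOL_NAMES = ("latent", "short_veg", "long_veg", "bourse_short", "bourse_long", "scar")

#: sentinel for log(0) in per-node emission tables; kept finite so that
#: cumulative-sum differences never produce NaN inside the kernels
_LOG_ZERO = -1.0e9
_IMPOSSIBLE_CUTOFF = -1.0e8


# ---------------------------------------------------------------------- #
# model specification
# ---------------------------------------------------------------------- #

@dataclass
class EmissionDist:
    """Categorical observation distribution with a support mask."""

    probs: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_SYMBOLS,):
            raise ConfigError("emission must have one probability per symbol")
        if self.mask is None:
            self.mask = self.probs > 0
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.probs[~self.mask] != 0):
            raise ConfigError("emission has mass outside its mask")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-9):
            raise ConfigError("emission probabilities must sum to 1")

    @classmethod
    def delta(cls, symbol: int) -> "EmissionDist":
        p = np.zeros(N_SYMBOLS)
        p[symbol] = 1.0
        return cls(p)

    @classmethod
    def from_dict(cls, weights: dict, mask: Iterable[int] | None = None) -> "EmissionDist":
        p = np.zeros(N_SYMBOLS)
        for k, v in weights.items():
            p[int(k)] = v
        p = p / p.sum()
        m = None
        if mask is not None:
            m = np.zeros(N_SYMBOLS, bool)
            m[list(mask)] = True
        return cls(p, m)

    @classmethod
    def uniform(cls, mask: Iterable[int]) -> "EmissionDist":
        m = np.zeros(N_SYMBOLS, bool)
        m[list(mask)] = True
        p = m / m.sum()
        return cls(p, m)

    @property
    def forced_symbol(self) -> int | None:
        if self.mask.sum() == 1:
            return int(np.flatnonzero(self.mask)[0])
        return None


@dataclass
class HSMMSpec:
    """Full left-to-right hidden semi-Markov chain specification.

    ``transitions`` has one row per transient state and ``n_states + 1``
    columns, the last being the absorbing end state.  Rows must be strictly
    upper-triangular among the transient states (left-to-right, transient).
    """

    initial: np.ndarray
    transitions: np.ndarray
    occupancies: list
    emissions: list
    state_names: list = None
    name: str = ""
    support_max: int = 150

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.state_names is None:
            self.state_names = [f"Z{i}" for i in range(self.n_states)]
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.occupancies)

    def validate(self) -> None:
        S = self.n_states
        if self.initial.shape != (S,):
            raise ConfigError("initial vector has wrong length")
        if self.transitions.shape != (S, S + 1):
            raise ConfigError("transition matrix must be (S, S+1)")
        if len(self.emissions) != S or len(self.state_names) != S:
            raise ConfigError("per-state lists must have length S")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-8):
            raise ConfigError("initial probabilities must sum to 1")
        if np.any(self.initial < 0) or np.any(self.transitions < 0):
            raise ConfigError("probabilities must be non-negative")
        rows = self.transitions.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ConfigError("each transition row must sum to 1")
        lower = np.tril(self.transitions[:, :S])
        if np.any(lower != 0):
            raise ConfigError("transitions must be strictly left-to-right (upper-triangular)")

    @property
    def forced_states(self) -> dict:
        """Mapping state index -> forced symbol for single-symbol states."""
        out = {}
        for i, e in enumerate(self.emissions):
            s = e.forced_symbol
            if s is not None:
                out[i] = s
        return out

    def mean_total_length(self, n_mc: int = 20000, seed: int = 0) -> float:
        """Monte-Carlo expected sequence length (nodes)."""
        seqs, _ = simulate(self, n_mc, seed)
        return float(np.mean([len(s) for s in seqs]))

    # -------------------------- serialization -------------------------- #
    def to_dict(self) -> dict:
        def f(x):
            return float(f"{float(x):.12g}")

        return {
            "name": self.name,
            "support_max": int(self.support_max),
            "state_names": list(self.state_names),
            "initial": [f(x) for x in self.initial],
            "transitions": [[f(x) for x in row] for row in self.transitions],
            "occupancies": [
                {"family": o.family, "params": {k: f(v) for k, v in o.params.items()}}
                for o in self.occupancies
            ],
            "emissions": [
                {
                    "probs": [f(x) for x in e.probs],
                    "mask": [int(i) for i in np.flatnonzero(e.mask)],
                }
                for e in self.emissions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HSMMSpec":
        occ = [OccupancyDist(o["family"], o["params"]) for o in d["occupancies"]]
        emi = []
        for e in d["emissions"]:
            m = np.zeros(N_SYMBOLS, bool)
            m[e["mask"]] = True
            emi.append(EmissionDist(np.asarray(e["probs"], float), m))
        return cls(
            initial=np.asarray(d["initial"], float),
            transitions=np.asarray(d["transitions"], float),
            occupancies=occ,
            emissions=emi,
            state_names=list(d["state_names"]),
            name=d.get("name", ""),
            support_max=int(d.get("support_max", 150)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "HSMMSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class DecodedPath:
    """Most probable segmentation of one sequence into zones."""

    symbols: np.ndarray
    states: np.ndarray
    log_joint: float
    shoot_id: str = ""


# ---------------------------------------------------------------------- #
# published model structures
# ---------------------------------------------------------------------- #

def monocyclic_template(mean_length: float = 10.0) -> HSMMSpec:
    """3+1-state template for monocyclic shoots with short/medium growth
    duration: basal latent zone S0 (latent buds only), diffuse floral zone
    S1, acrotonic vegetative zone S2, absorbing end S3.

    Positive cells mark the free parameters for EM; the probability values
    themselves are just a neutral starting point.
    """
    m = max(mean_length / 3.0, 2.0)
    trans = np.array([
        [0.0, 1 / 3, 1 / 3, 1 / 3],
        [0.0, 0.0, 1 / 2, 1 / 2],
        [0.0, 0.0, 0.0, 1.0],
    ])
    free = EmissionDist.uniform([0, 1, 2, 3, 4])
    # negative binomial occupancies: zone lengths pooled across shoot
    # categories are overdispersed, and the family nests the Poisson
    return HSMMSpec(
        initial=np.array([1.0, 0.0, 0.0]),
        transitions=trans,
        occupancies=[OccupancyDist.shifted_negbin(m, 2.0) for _ in range(3)],
        emissions=[EmissionDist.delta(0), free, free],
        state_names=["S0", "S1", "S2"],
        name="one-GU-short-medium",
    )


def combined_template(mean_length: float = 25.0) -> HSMMSpec:
    """7+1-state template for monocyclic long-GD and bicyclic shoots.

    L0 basal latent (forced latent), L1 diffuse floral, L2 cessation zone
    (forced bud-scar, bicyclic shoots only), L3 second-GU latent (forced
    latent), L4 short shoot zone, L5 floral zone, L6 acrotonic vegetative
    zone, absorbing end L7.  Monocyclic long-GD shoots bypass the scar via
    the L1 -> L3 transition.
    """
    S = 7
    trans = np.zeros((S, S + 1))
    allowed = {
        0: [1, 2],
        1: [2, 3],
        2: [3],
        3: [4, 5, 6, 7],
        4: [5, 6, 7],
        5: [6, 7],
        6: [7],
    }
    for i, js in allowed.items():
        trans[i, js] = 1.0 / len(js)
    m = max(mean_length / 5.0, 2.0)
    free = EmissionDist.uniform([0, 1, 2, 3, 4])
    occ = [OccupancyDist.shifted_negbin(m, 2.0) for _ in range(S)]
    emis = [
        EmissionDist.delta(0),   # L0
        free,                    # L1
        EmissionDist.delta(5),   # L2 bud scars
        EmissionDist.delta(0),   # L3
        free,                    # L4
        free,                    # L5
        free,                    # L6
    ]
    init = np.zeros(S)
    init[0] = 1.0
    return HSMMSpec(init, trans, occ, emis,
                    state_names=[f"L{i}" for i in range(S)],
                    name="one-GU-long-and-two-GUs")


# ---------------------------------------------------------------------- #
# numeric tables and elementary operations
# ---------------------------------------------------------------------- #

def _as_symbols(seq) -> np.ndarray:
    sym = getattr(seq, "symbols", seq)
    arr = np.asarray(sym, dtype=np.int64)
    if arr.ndim != 1 or arr.size == 0:
        raise DataError("sequence must be a non-empty 1-d symbol array")
    bad = (arr < 0) | (arr >= N_SYMBOLS)
    if np.any(bad):
        raise DataError(f"symbol outside alphabet at node {int(np.flatnonzero(bad)[0])}")
    return arr


def _tables(spec: HSMMSpec):
    S = spec.n_states
    with np.errstate(divide="ignore"):
        logpi = np.where(spec.initial > 0, np.log(spec.initial), -np.inf)
        At = spec.transitions[:, :S]
        logAt = np.where(At > 0, np.log(np.maximum(At, 1e-300)), -np.inf)
        Ae = spec.transitions[:, S]
        logAe = np.where(Ae > 0, np.log(np.maximum(Ae, 1e-300)), -np.inf)
    logD = np.vstack([o.log_pmf_vector(spec.support_max) for o in spec.occupancies])
    logD = np.where(np.isfinite(logD), logD, -np.inf)
    logE = np.full((S, N_SYMBOLS), _LOG_ZERO)
    for j, e in enumerate(spec.emissions):
        nz = e.probs > 0
        logE[j, nz] = np.log(e.probs[nz])
    return logpi, logAt, logAe, logD, logE


def _logB(logE: np.ndarray, symbols: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(logE[:, symbols])


def log_likelihood(spec: HSMMSpec, seq) -> float:
    """log P(sequence, termination exactly at its end); -inf if impossible."""
    symbols = _as_symbols(seq)
    logpi, logAt, logAe, logD, logE = _tables(spec)
    *_, ll = _recursions.forward(logpi, logAt, logAe, logD, _logB(logE, symbols))
    return -np.inf if ll < _IMPOSSIBLE_CUTOFF else float(ll)


def viterbi_decode(spec: HSMMSpec, seq) -> DecodedPath:
    """Explicit-duration Viterbi restoration of the most probable zones."""
    symbols = _as_symbols(seq)
    logpi, logAt, logAe, logD, logE = _tables(spec)
    states, score = _recursions.viterbi(logpi, logAt, logAe, logD, _logB(logE, symbols))
    if states.size == 0 or score < _IMPOSSIBLE_CUTOFF:
        # locate the first node that cannot be emitted by any state
        emittable = np.any(np.vstack([e.probs for e in spec.emissions]) > 0, axis=0)
        bad = np.flatnonzero(~emittable[symbols])
        node = int(bad[0]) if bad.size else 0
        raise DataError(f"sequence impossible under the model (first inconsistent node {node})")
    return DecodedPath(symbols, states, float(score),
                       shoot_id=getattr(seq, "shoot_id", ""))


def simulate(spec: HSMMSpec, n: int, seed=None) -> tuple[list, list]:
    """Draw ``n`` i.i.d. sequences; returns (symbol arrays, per-node states)."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = spec.n_states
    seqs, paths = [], []
    for _ in range(n):
        sym_parts, state_parts = [], []
        j = int(rng.choice(S, p=spec.initial))
        while True:
            d = int(spec.occupancies[j].sample(rng, 1)[0])
            d = min(d, spec.support_max)
            sym_parts.append(rng.choice(N_SYMBOLS, size=d, p=spec.emissions[j].probs))
            state_parts.append(np.full(d, j, dtype=np.int64))
            nxt = int(rng.choice(S + 1, p=spec.transitions[j]))
            if nxt == S:
                break
            j = nxt
        seqs.append(np.concatenate(sym_parts))
        paths.append(np.concatenate(state_parts))
    return seqs, paths


# ---------------------------------------------------------------------- #
# EM estimation
# ---------------------------------------------------------------------- #

@dataclass
class EMSettings:
    n_restarts: int = 10
    tol: float = 1e-6
    max_iter: int = 500
    seed: int | None = None
    emission_floor: float = 1e-6


def _init_spec(structure: HSMMSpec, seqs: list, rng: np.random.Generator,
               jitter: bool) -> HSMMSpec:
    """Starting point: uniform transitions over permitted cells, emissions
    from positional symbol frequencies under the masks (state j is seeded
    from the j-th fraction of each sequence, the natural prior for a
    left-to-right chain; floor 1e-3), occupancy means at mean sequence
    length / state count; restarts > 0 are jittered.
    """
    S = structure.n_states
    spec = copy.deepcopy(structure)
    pos_freq = np.full((S, N_SYMBOLS), 1e-3)
    for s in seqs:
        blocks = np.minimum((np.arange(len(s)) * S) // max(len(s), 1), S - 1)
        np.add.at(pos_freq, (blocks, s), 1.0)
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    mean_len = float(np.mean([len(s) for s in seqs]))
    mean_occ = max(mean_len / S, 1.3)
    for j in range(S):
        mask = structure.emissions[j].mask
        if mask.sum() > 1:
            if jitter:
                # flat Dirichlet over the mask: restarts explore basins the
                # data frequencies (often dominated by latent buds) miss
                p = np.zeros(N_SYMBOLS)
                p[mask] = rng.dirichlet(np.ones(int(mask.sum())))
                p = np.maximum(p, 1e-3)
                p[~mask] = 0.0
            else:
                p = np.where(mask, np.maximum(pos_freq[j], 1e-3), 0.0)
            spec.emissions[j] = EmissionDist(p / p.sum(), mask)
        occ = structure.occupancies[j]
        m = mean_occ * (np.exp(rng.normal(0.0, 0.25)) if jitter else 1.0)
        if occ.family == "shifted-poisson":
            spec.occupancies[j] = OccupancyDist.shifted_poisson(max(m, 1.1))
        elif occ.family == "shifted-negbin":
            spec.occupancies[j] = OccupancyDist.shifted_negbin(max(m, 1.5), 2.0)
        elif occ.family == "shifted-binomial":
            n_ = max(int(np.ceil(2 * m)), 2)
            spec.occupancies[j] = OccupancyDist.shifted_binomial(n_, min(m / n_, 0.95))
        # point mass kept as declared
        row = (structure.transitions[j] > 0).astype(float)
        if row.sum() > 0:
            if jitter:
                row = row * np.exp(rng.normal(0.0, 0.3, size=S + 1))
                row[structure.transitions[j] <= 0] = 0.0
            spec.transitions[j] = row / row.sum()
    if np.count_nonzero(structure.initial) > 1:
        p = (structure.initial > 0).astype(float)
        spec.initial = p / p.sum()
    spec.validate()
    return spec


def _em_one_run(seqs, structure, spec, settings: EMSettings):
    S = structure.n_states
    init_mask = structure.initial > 0
    trans_mask = structure.transitions > 0
    Dmax = spec.support_max
    trace = []
    prev_ll = -np.inf
    n_iter = 0
    converged = False
    for it in range(settings.max_iter):
        logpi, logAt, logAe, logD, logE = _tables(spec)
        init_post = np.zeros(S)
        trans_post = np.zeros((S, S))
        end_post = np.zeros(S)
        dur_post = np.zeros((S, Dmax))
        emis_counts = np.zeros((S, N_SYMBOLS))
        total_ll = 0.0
        for symbols in seqs:
            gamma = np.zeros((S, len(symbols)))
            ll = _recursions.estep(logpi, logAt, logAe, logD, _logB(logE, symbols),
                                   init_post, trans_post, end_post, dur_post, gamma)
            if ll < _IMPOSSIBLE_CUTOFF:
                raise DataError("sequence impossible under the model structure")
            total_ll += ll
            for v in range(N_SYMBOLS):
                cols = symbols == v
                if np.any(cols):
                    emis_counts[:, v] += gamma[:, cols].sum(axis=1)
        trace.append(total_ll)
        n_iter = it + 1

        # ---- M-step ----
        if init_mask.sum() > 1:
            tot = init_post.sum()
            if tot > 0:
                p = np.where(init_mask, init_post, 0.0)
                spec.initial = p / p.sum()
        for j in range(S):
            row = np.zeros(S + 1)
            row[:S] = np.where(trans_mask[j, :S], trans_post[j], 0.0)
            if trans_mask[j, S]:
                row[S] = end_post[j]
            tot = row.sum()
            if tot > 1e-12:
                spec.transitions[j] = row / tot
            mask = structure.emissions[j].mask
            if mask.sum() > 1:
                c = np.where(mask, emis_counts[j], 0.0)
                if c.sum() > 1e-12:
                    p = c / c.sum()
                    p = np.where(mask, np.maximum(p, settings.emission_floor), 0.0)
                    spec.emissions[j] = EmissionDist(p / p.sum(), mask)
            wtot = dur_post[j].sum()
            if wtot > 1e-10:
                fam = structure.occupancies[j].family
                spec.occupancies[j] = fit_family(
                    np.arange(1, Dmax + 1), fam, weights=dur_post[j])

        if it > 0:
            denom = max(abs(prev_ll), 1.0)
            if total_ll < prev_ll - 1e-8 * denom:
                logger.warning("EM log-likelihood decreased by %.3g at iter %d",
                               prev_ll - total_ll, it)
            if abs(total_ll - prev_ll) / denom < settings.tol:
                converged = True
                break
        prev_ll = total_ll
    return spec, trace, n_iter, converged


def _free_param_count(structure: HSMMSpec) -> int:
    k = 0
    nz_init = int(np.count_nonzero(structure.initial))
    if nz_init > 1:
        k += nz_init - 1
    for j in range(structure.n_states):
        nz = int(np.count_nonzero(structure.transitions[j]))
        k += max(nz - 1, 0)
        nz_e = int(structure.emissions[j].mask.sum())
        k += max(nz_e - 1, 0)
        k += structure.occupancies[j].n_params
    return k


class HSMMResults:
    """Fitted hidden semi-Markov chain (estimates, fit diagnostics)."""

    def __init__(self, model, spec, loglik, n_iter, bic, restart_id,
                 converged, loglik_trace):
        self.model = model
        self.spec = spec
        self.loglik = loglik
        self.n_iter = n_iter
        self.bic = bic
        self.restart_id = restart_id
        self.converged = converged
        self.loglik_trace = loglik_trace

    def decode(self, sequences=None) -> list:
        seqs = self.model.raw_sequences if sequences is None else sequences
        return [viterbi_decode(self.spec, s) for s in seqs]

    def simulate(self, n: int, seed=None):
        return simulate(self.spec, n, seed)

    def summary(self) -> str:
        sp = self.spec
        lines = [
            f"Hidden semi-Markov chain: {sp.name or '(unnamed)'}",
            f"  transient states: {sp.n_states}   log-likelihood: {self.loglik:.3f}",
            f"  BIC: {self.bic:.3f}   EM iterations: {self.n_iter}"
            f"   restart: {self.restart_id}   converged: {self.converged}",
            "",
            f"{'state':>6} {'occupancy':>18} {'mean':>7}  emission (symbol:prob)",
        ]
        for j, name in enumerate(sp.state_names):
            occ = sp.occupancies[j]
            em = sp.emissions[j]
            ps = " ".join(
                f"{v}:{em.probs[v]:.3f}" for v in range(N_SYMBOLS) if em.probs[v] > 0
            )
            lines.append(f"{name:>6} {occ.family:>18} {occ.mean():7.2f}  {ps}")
        lines.append("")
        lines.append("transitions (row -> col, 'end' last):")
        header = "        " + " ".join(f"{n:>7}" for n in sp.state_names + ["end"])
        lines.append(header)
        for j, name in enumerate(sp.state_names):
            row = " ".join(f"{p:7.3f}" for p in sp.transitions[j])
            lines.append(f"{name:>7} {row}")
        return "\n".join(lines)


class HiddenSemiMarkovModel:
    """Left-to-right explicit-duration chain built from bud-fate sequences.

    Parameters
    ----------
    sequences : iterable of symbol arrays or BranchingSequence objects
    structure : HSMMSpec
        Structural template; its zero pattern (initial vector, transition
        matrix, emission masks) defines the constraints, its occupancy
        families the duration models.
    """

    def __init__(self, sequences, structure: HSMMSpec):
        self.raw_sequences = list(sequences)
        self.sequences = [_as_symbols(s) for s in self.raw_sequences]
        if not self.sequences:
            raise DataError("at least one sequence is required")
        self.structure = structure
        structure.validate()
        self.total_nodes = int(sum(len(s) for s in self.sequences))

    @classmethod
    def from_sequences(cls, branching_sequences, structure):
        return cls(branching_sequences, structure)

    def loglike(self, spec: HSMMSpec) -> float:
        return float(sum(log_likelihood(spec, s) for s in self.sequences))

    def fit(self, settings: EMSettings | None = None, **kwargs) -> HSMMResults:
        if settings is None:
            settings = EMSettings(**kwargs)
        elif kwargs:
            raise ConfigError("pass either an EMSettings or keyword settings")
        rng = np.random.default_rng(settings.seed)
        best = None
        for r in range(settings.n_restarts):
            start = _init_spec(self.structure, self.sequences, rng, jitter=r > 0)
            try:
                spec, trace, n_iter, converged = _em_one_run(
                    self.sequences, self.structure, start, settings)
            except DataError:
                raise
            except (FloatingPointError, ValueError) as exc:  # degenerate restart
                logger.warning("EM restart %d discarded: %s", r, exc)
                continue
            if best is None or trace[-1] > best[1][-1]:
                best = (spec, trace, n_iter, converged, r)
        if best is None:
            raise DataError("all EM restarts degenerated")
        spec, trace, n_iter, converged, restart_id = best
        # drop free emission cells that stayed at the numerical floor
        for j in range(spec.n_states):
            e = spec.emissions[j]
            if e.mask.sum() > 1:
                p = np.where(e.probs <= settings.emission_floor * 1.0001, 0.0, e.probs)
                if p.sum() > 0 and not np.array_equal(p, e.probs):
                    spec.emissions[j] = EmissionDist(p / p.sum(), e.mask)
        loglik = self.loglike(spec)
        k = _free_param_count(self.structure)
        bic = -2.0 * loglik + k * np.log(self.total_nodes)
        return HSMMResults(self, spec, loglik, n_iter, bic, restart_id,
                           converged, trace)


def fit_em(sequences, structure: HSMMSpec,
           settings: EMSettings | None = None, **kwargs) -> HSMMResults:
    """EM estimation under structural constraints (best of random restarts)."""
    return HiddenSemiMarkovModel(sequences, structure).fit(settings, **kwargs)
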