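"""From decoded paths to the comparison layer: zones, occurrence
probabilities, zone-length tests, lateral-type distributions, correlations.

"Occurrence" of a zone is operationalised as presence of its state in the
restored (Viterbi) path; zone lengths are compared with a negative binomial
GLM, lateral-type distributions with Fisher's exact test, and the relation
between zone length and total shoot length with a Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
import statsmodels.api as sm

from .errors import DataError
from .hsmm import DecodedPath

logger = logging.getLogger("shootzones")


def significance_code(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------- #
# zones
# ---------------------------------------------------------------------- #

@dataclass
class Zone:
    """One maximal run of a state: half-open node span [start, end)."""

    state: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ZoneProfile:
    """Ordered zones partitioning one decoded shoot."""

    shoot_id: str
    zones: list
    symbols: np.ndarray

    @property
    def states_visited(self) -> set:
        return {z.state for z in self.zones}

    @property
    def total_nodes(self) -> int:
        return int(self.symbols.size)

    def zone_length(self, state: int) -> int | None:
        for z in self.zones:
            if z.state == state:
                return z.length
        return None


def extract_zones(path: DecodedPath) -> ZoneProfile:
    """Run-length encode a decoded state path into zones."""
    states = np.asarray(path.states)
    if states.size == 0:
        raise DataError("empty decoded path")
    if np.any(np.diff(states) < 0):
        raise DataError("decoded states must be non-decreasing")
    bounds = np.flatnonzero(np.diff(states)) + 1
    edges = np.concatenate([[0], bounds, [states.size]])
    zones = [Zone(int(states[a]), int(a), int(b)) for a, b in zip(edges, edges[1:])]
    return ZoneProfile(path.shoot_id, zones, np.asarray(path.symbols))


# ---------------------------------------------------------------------- #
# occurrence probabilities
# ---------------------------------------------------------------------- #

def occurrence_probabilities(profiles_by_group: dict, states,
                             state_names=None) -> pd.DataFrame:
    """Per-group fraction of shoots whose restored path visits each state."""
    states = list(states)
    names = state_names or [str(s) for s in states]
    rows = []
    for group, profiles in profiles_by_group.items():
        if not profiles:
            raise DataError(f"group {group!r} is empty")
        row = {"group": group, "n": len(profiles)}
        for s, nm in zip(states, names):
            row[nm] = float(np.mean([s in p.states_visited for p in profiles]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------- #
# zone-length comparison (negative binomial GLM)
# ---------------------------------------------------------------------- #

@dataclass
class ZoneComparisonResult:
    state: int
    groups: tuple
    statistic: float | None
    pvalue: float | None
    code: str
    family: str = "negative-binomial"
    performed: bool = True
    note: str = ""


def compare_zone_lengths(lengths_a, lengths_b, state: int = -1,
                         groups: tuple = ("A", "B")) -> ZoneComparisonResult:
    """Wald test of the group effect in a log-link count GLM of zone length.

    The negative binomial model is fitted by maximum likelihood; if it fails
    to converge a Poisson GLM is used and flagged.  Groups with fewer than 3
    zones give a no-test result.
    """
    a = np.asarray(lengths_a, float)
    b = np.asarray(lengths_b, float)
    if a.size < 3 or b.size < 3:
        return ZoneComparisonResult(state, groups, None, None, "─",
                                    performed=False,
                                    note="fewer than 3 zones in a group")
    y = np.concatenate([a, b])
    X = sm.add_constant(np.concatenate([np.zeros(a.size), np.ones(b.size)]))
    if np.all(y == y[0]):
        return ZoneComparisonResult(state, groups, 0.0, 1.0, "ns",
                                    note="constant lengths")
    try:
        with np.errstate(all="ignore"):
            res = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        if not np.isfinite(res.bse[1]):
            converged = False
    except Exception:
        converged = False
    if converged:
        z = float(res.params[1] / res.bse[1])
        p = 2 * stats.norm.sf(abs(z))
        return ZoneComparisonResult(state, groups, z, float(p), significance_code(p))
    logger.warning("NB GLM did not converge for state %s; falling back to Poisson", state)
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    z = float(res.params[1] / res.bse[1])
    p = 2 * stats.norm.sf(abs(z))
    return ZoneComparisonResult(state, groups, z, float(p), significance_code(p),
                                family="poisson", note="NB fit did not converge")


# ---------------------------------------------------------------------- #
# Fisher's exact test for r x c tables
# ---------------------------------------------------------------------- #

@dataclass
class FisherResult:
    pvalue: float
    method: str  # "exact-2x2", "exact-enumeration", "monte-carlo"
    n_tables: int = 0
    monte_carlo: bool = False


def _log_table_prob(table: np.ndarray, logfact_margins: float, logN: float) -> float:
    return logfact_margins - logN - gammaln(table + 1.0).sum()


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(i, cols_left, rows):
        if i == r - 1:
            last = np.asarray(cols_left)
            if np.all(last >= 0):
                yield rows + [last]
            return
        target = row_sums[i]

        def fill(j, remaining, current):
            if j == c - 1:
                if 0 <= remaining <= cols_left[j]:
                    yield current + [remaining]
                return
            hi = min(remaining, cols_left[j])
            for v in range(hi + 1):
                yield from fill(j + 1, remaining - v, current + [v])

        for row in fill(0, target, []):
            nxt = [cl - v for cl, v in zip(cols_left, row)]
            yield from rec(i + 1, nxt, rows + [np.asarray(row)])

    yield from rec(0, list(col_sums), [])


MC_DRAWS = 100_000
MC_SEED = 20160603  # fixed: Monte-Carlo p-values must be reproducible
_ENUM_TOTAL_MAX = 200
_ENUM_TABLE_CAP = 2_000_000


def _enumeration_size(row_sums, col_sums) -> float:
    # crude upper bound on the number of tables
    bound = 1.0
    for _ in range(len(row_sums) - 1):
        for c in col_sums:
            bound *= (min(c, max(row_sums)) + 1)
    return bound


def compare_lateral_distributions(table) -> FisherResult:
    """Fisher's exact test of independence for a lateral-type contingency
    table (groups x symbol classes).

    2x2 tables use the exact hypergeometric test; larger tables are
    enumerated exhaustively when the total count is at most 200 (and the
    enumeration is tractable), otherwise a Monte-Carlo exact test with
    100,000 Patefield draws and a fixed seed is used and flagged.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2:
        raise DataError("contingency table must be 2-d")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise DataError("need at least 2 non-empty rows and columns")
    if t.shape == (2, 2):
        _, p = stats.fisher_exact(t)
        return FisherResult(float(min(p, 1.0)), "exact-2x2")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    N = int(t.sum())
    logfact_margins = gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum()
    logN = gammaln(N + 1.0)
    logp_obs = _log_table_prob(t, logfact_margins, logN)
    if N <= _ENUM_TOTAL_MAX and _enumeration_size(rows, cols) <= _ENUM_TABLE_CAP:
        total = 0.0
        count = 0
        for tab in _enumerate_tables(rows, cols):
            count += 1
            lp = _log_table_prob(np.vstack(tab), logfact_margins, logN)
            if lp <= logp_obs + 1e-7:
                total += np.exp(lp)
        return FisherResult(float(min(total, 1.0)), "exact-enumeration", count)
    rng = np.random.default_rng(MC_SEED)
    draws = stats.random_table(rows, cols).rvs(MC_DRAWS, random_state=rng)
    lps = logfact_margins - logN - gammaln(draws + 1.0).sum(axis=(1, 2))
    p = float((np.sum(lps <= logp_obs + 1e-7) + 1) / (MC_DRAWS + 1))
    return FisherResult(min(p, 1.0), "monte-carlo", MC_DRAWS, monte_carlo=True)


# ---------------------------------------------------------------------- #
# zone length vs total length
# ---------------------------------------------------------------------- #

@dataclass
class CorrelationResult:
    state: int
    n: int
    r: float | None
    r_squared: float | None
    pvalue: float | None = None
    note: str = ""


def correlate_zone_vs_total(profiles, state: int,
                            scope=None) -> CorrelationResult:
    """Pearson correlation between a zone's length and total node number,
    restricted to shoots that possess the zone.

    ``scope`` optionally maps a profile to the node count of interest
    (e.g. first-GU nodes only); by default the whole shoot is used.
    """
    xs, ys = [], []
    for p in profiles:
        zl = p.zone_length(state)
        if zl is None:
            continue
        total = scope(p) if scope is not None else p.total_nodes
        xs.append(zl)
        ys.append(total)
    n = len(xs)
    if n < 3:
        return CorrelationResult(state, n, None, None,
                                 note="fewer than 3 shoots possess the zone")
    x, y = np.asarray(xs, float), np.asarray(ys, float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationResult(state, n, None, None, note="zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(state, n, float(r), float(r * r), float(p))


# ---------------------------------------------------------------------- #
# tabular outputs
# ---------------------------------------------------------------------- #

def zone_comparison_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "state": r.state,
            "group_a": r.groups[0],
            "group_b": r.groups[1],
            "statistic": r.statistic,
            "pvalue": r.pvalue,
            "code": r.code,
            "family": r.family if r.performed else "",
            "note": r.note,
        })
    return pd.DataFrame(rows)


def lateral_type_distribution(profiles, state: int,
                              include_scar: bool = False) -> np.ndarray:
    """Pooled symbol counts within one state across profiles (lateral types
    0..4; scar nodes excluded unless requested)."""
    n_sym = 6 if include_scar else 5
    counts = np.zeros(n_sym, dtype=np.int64)
    for p in profiles:
        for z in p.zones:
            if z.state != state:
                continue
            seg = p.symbols[z.start:z.end]
            for v in range(n_sym):
                counts[v] += int(np.sum(seg == v))
    return counts
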