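"""Category-level comparisons of node numbers and lateral-type counts.

Count outcomes (nodes per shoot, laterals per shoot) are compared with a
log-link count GLM — Poisson unless a chi-square goodness-of-fit test
rejects it, then negative binomial — followed by all pairwise contrasts
with a single-step (Tukey-style, max-|z| multivariate normal) adjustment
and a compact letter display.  Rank-based alternatives (Mann-Whitney for
two groups, Kruskal-Wallis with Dunn/Holm post hoc otherwise) and
contingency comparisons (chi-square, or Fisher's exact test when expected
cells are small) cover the non-GLM comparisons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .zones import compare_lateral_distributions, significance_code

logger = logging.getLogger("shootzones")


# ---------------------------------------------------------------------- #
# count family selection
# ---------------------------------------------------------------------- #

@dataclass
class FamilySelection:
    family: str               # "poisson" | "negative-binomial"
    chi2: float
    dof: int
    pvalue: float
    note: str = ""


def select_count_family(counts, alpha: float = 0.05) -> FamilySelection:
    """Pearson chi-square goodness of fit of a Poisson law to the counts.

    Bins with small Poisson expectation are pooled into the tails so every
    expected count is at least 5 where possible.  Rejection at ``alpha``
    selects the negative binomial family.
    """
    y = np.asarray(counts, dtype=np.int64)
    if y.size < 10:
        raise DataError("need at least 10 counts to select a family")
    if np.all(y == y[0]):
        # degenerate variance: Poisson is formally rejected by any
        # dispersion logic, but a chi-square cannot be formed — keep Poisson
        return FamilySelection("poisson", 0.0, 0, 1.0, "constant counts")
    mu = y.mean()
    hi = int(y.max())
    ks = np.arange(hi + 1)
    probs = stats.poisson.pmf(ks, mu)
    probs[-1] += stats.poisson.sf(hi, mu)
    obs = np.bincount(y, minlength=hi + 1).astype(float)
    # pool adjacent bins until expected >= 5
    exp = probs * y.size
    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and pooled_exp:
        pooled_obs[-1] += acc_o
        pooled_exp[-1] += acc_e
    pooled_obs = np.asarray(pooled_obs)
    pooled_exp = np.asarray(pooled_exp)
    dof = max(len(pooled_obs) - 1 - 1, 1)  # one estimated parameter (mean)
    chi2 = float(np.sum((pooled_obs - pooled_exp) ** 2 / pooled_exp))
    p = float(stats.chi2.sf(chi2, dof))
    fam = "negative-binomial" if p < alpha else "poisson"
    return FamilySelection(fam, chi2, dof, p)


# ---------------------------------------------------------------------- #
# compact letter display
# ---------------------------------------------------------------------- #

def compact_letter_display(groups, significant_pairs) -> dict:
    """Insert-and-absorb letters: groups share a letter iff never separated
    by a significant pair."""
    letters: list[set] = [set(groups)]
    for a, b in significant_pairs:
        new = []
        for s in letters:
            if a in s and b in s:
                new.append(s - {a})
                new.append(s - {b})
            else:
                new.append(s)
        # absorb subsets
        new.sort(key=len, reverse=True)
        letters = []
        for s in new:
            if s and not any(s <= t for t in letters):
                letters.append(s)
    letters.sort(key=lambda s: sorted(groups.index(g) for g in s)[0]
                 if isinstance(groups, list) else sorted(s)[0])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letters):
        for g in s:
            out[g] += alphabet[i]
    return {g: "".join(sorted(v)) for g, v in out.items()}


# ---------------------------------------------------------------------- #
# node-number comparison: count GLM + single-step pairwise contrasts
# ---------------------------------------------------------------------- #

@dataclass
class PairwiseResult:
    pair: tuple
    estimate: float
    statistic: float
    pvalue: float       # single-step adjusted
    code: str


@dataclass
class NodeComparisonResult:
    family: str
    omnibus_pvalue: float | None
    pairwise: list
    letters: dict
    group_means: dict
    selection: FamilySelection | None = None

    def summary(self) -> pd.DataFrame:
        rows = [{"group": g, "mean": m, "letter": self.letters[g]}
                for g, m in self.group_means.items()]
        return pd.DataFrame(rows)


def _single_step_adjust(z: np.ndarray, R: np.ndarray) -> np.ndarray:
    """P(max_k |Z_k| >= |z_i|) under Z ~ N(0, R) (Tukey-style single step)."""
    K = len(z)
    R = (R + R.T) / 2 + 1e-9 * np.eye(K)
    mvn = stats.multivariate_normal(mean=np.zeros(K), cov=R, allow_singular=True)
    out = np.empty(K)
    for i, zi in enumerate(np.abs(z)):
        lo, hi = np.full(K, -zi), np.full(K, zi)
        inside = float(mvn.cdf(hi, lower_limit=lo))
        out[i] = min(max(1.0 - inside, 0.0), 1.0)
    return out


def compare_node_numbers(groups: dict, alpha: float = 0.05) -> NodeComparisonResult:
    """Count GLM of node number on category with Tukey-style post hoc.

    ``groups`` maps category label -> array of counts (each of size >= 3).
    The family is Poisson unless the goodness-of-fit test rejects it for
    any group, then negative binomial.  All pairwise contrasts are adjusted
    single-step; the compact letter display joins groups not significantly
    different at ``alpha``.
    """
    names = list(groups)
    if len(names) < 2:
        raise DataError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size < 3 for a in arrays):
        raise DataError("each group needs at least 3 observations")
    selection = None
    family = "poisson"
    for a in arrays:
        if a.size >= 10:
            sel = select_count_family(a.astype(np.int64))
            selection = selection or sel
            if sel.family == "negative-binomial":
                family, selection = "negative-binomial", sel
                break
    y = np.concatenate(arrays)
    labels = np.concatenate([np.full(a.size, i) for i, a in enumerate(arrays)])
    X = np.zeros((y.size, len(names)))
    X[np.arange(y.size), labels.astype(int)] = 1.0  # cell-means coding
    if family == "negative-binomial":
        with np.errstate(all="ignore"):
            nb = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
        alpha_hat = max(float(nb.params[-1]), 1e-8)
        res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha_hat)).fit()
    else:
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    pairs = list(itertools.combinations(range(len(names)), 2))
    L = np.zeros((len(pairs), len(names)))
    for k, (i, j) in enumerate(pairs):
        L[k, i], L[k, j] = 1.0, -1.0
    est = L @ params
    V = L @ cov @ L.T
    se = np.sqrt(np.diag(V))
    zstat = est / se
    R = V / np.outer(se, se)
    if len(pairs) == 1:
        padj = 2 * stats.norm.sf(np.abs(zstat))
    else:
        padj = _single_step_adjust(zstat, R)
    pairwise = [
        PairwiseResult((names[i], names[j]), float(est[k]), float(zstat[k]),
                       float(padj[k]), significance_code(padj[k]))
        for k, (i, j) in enumerate(pairs)
    ]
    sig = [(names[i], names[j]) for k, (i, j) in enumerate(pairs) if padj[k] < alpha]
    letters = compact_letter_display(names, sig)
    # omnibus: Wald test that all group means are equal
    C = np.zeros((len(names) - 1, len(names)))
    for k in range(len(names) - 1):
        C[k, 0], C[k, k + 1] = 1.0, -1.0
    w = C @ params
    Vw = C @ cov @ C.T
    chi2 = float(w @ np.linalg.solve(Vw, w))
    omnibus = float(stats.chi2.sf(chi2, len(names) - 1))
    means = {g: float(a.mean()) for g, a in zip(names, arrays)}
    return NodeComparisonResult(family, omnibus, pairwise, letters, means, selection)


# ---------------------------------------------------------------------- #
# rank-based comparisons of lateral counts
# ---------------------------------------------------------------------- #

@dataclass
class RankTestResult:
    test: str
    statistic: float
    pvalue: float
    code: str
    posthoc: list = field(default_factory=list)   # (pair, z, p_holm, code)


def _dunn_posthoc(arrays, names, alpha=0.05):
    """Dunn's z tests on mean ranks with tie correction, Holm-adjusted."""
    all_vals = np.concatenate(arrays)
    N = all_vals.size
    ranks = stats.rankdata(all_vals)
    splits = np.cumsum([a.size for a in arrays])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [g.mean() for g in group_ranks]
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    pairs, zs = [], []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        pairs.append((names[i], names[j]))
        zs.append(z)
    praw = 2 * stats.norm.sf(np.abs(zs))
    _, padj, _, _ = multipletests(praw, method="holm")
    return [(pair, float(z), float(p), significance_code(p))
            for pair, z, p in zip(pairs, zs, padj)]


def compare_lateral_counts(groups: dict, alpha: float = 0.05) -> RankTestResult:
    """Mann-Whitney (2 groups) or Kruskal-Wallis with Dunn/Holm post hoc.

    All-tied data gives a defined null result (p = 1, no post hoc).
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2 or any(a.size < 3 for a in arrays):
        raise DataError("need >= 2 groups of >= 3 observations")
    all_vals = np.concatenate(arrays)
    if np.all(all_vals == all_vals[0]):
        test = "mann-whitney" if len(arrays) == 2 else "kruskal-wallis"
        return RankTestResult(test, 0.0, 1.0, "ns")
    if len(arrays) == 2:
        u, p = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided",
                                  use_continuity=True)
        return RankTestResult("mann-whitney", float(u), float(p), significance_code(p))
    h, p = stats.kruskal(*arrays)
    posthoc = _dunn_posthoc(arrays, names, alpha) if p < alpha else []
    return RankTestResult("kruskal-wallis", float(h), float(p),
                          significance_code(p), posthoc)


# ---------------------------------------------------------------------- #
# lateral-type proportions
# ---------------------------------------------------------------------- #

@dataclass
class ProportionTestResult:
    test: str                    # "chi-square" | "fisher"
    statistic: float | None
    pvalue: float
    code: str
    flagged_small: bool = False
    posthoc: list = field(default_factory=list)


def compare_lateral_proportions(table, group_axis: int = 0,
                                alpha: float = 0.05) -> ProportionTestResult:
    """Chi-square test of homogeneity of lateral-type composition across
    groups; routes to Fisher's exact test when any expected cell is < 5.

    ``table`` is a groups x lateral-types contingency table (set
    ``group_axis=1`` if transposed).  A significant chi-square is followed
    by Holm-adjusted pairwise chi-square tests on the 2 x k sub-tables.
    """
    t = np.asarray(table, dtype=np.int64)
    if group_axis == 1:
        t = t.T
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DataError("table must be at least 2x2")
    keep_cols = t.sum(axis=0) > 0
    t = t[:, keep_cols]
    if t.shape[1] < 2:
        raise DataError("fewer than 2 non-empty lateral-type columns")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if np.any(expected < 5):
        fr = compare_lateral_distributions(t)
        return ProportionTestResult("fisher", None, fr.pvalue,
                                    significance_code(fr.pvalue),
                                    flagged_small=True)
    chi2, p, dof, _ = stats.chi2_contingency(t)
    posthoc = []
    if p < alpha and t.shape[0] > 2:
        pairs = list(itertools.combinations(range(t.shape[0]), 2))
        praw = []
        for i, j in pairs:
            sub = t[[i, j]]
            sub = sub[:, sub.sum(axis=0) > 0]
            praw.append(stats.chi2_contingency(sub)[1])
        _, padj, _, _ = multipletests(praw, method="holm")
        posthoc = [((i, j), float(p_), significance_code(p_))
                   for (i, j), p_ in zip(pairs, padj)]
    return ProportionTestResult("chi-square", float(chi2), float(p),
                                significance_code(p), posthoc=posthoc)
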