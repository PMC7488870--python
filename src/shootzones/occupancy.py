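"""State-occupancy (zone-length) distributions for explicit-duration chains.

A branching zone occupies at least one node, so every family lives on
``d = 1, 2, ...`` (a unit shift of the usual count distribution).  Four
families are supported:

* ``point`` — degenerate at a single length;
* ``shifted-poisson`` — ``d = 1 + Poisson(mu)``;
* ``shifted-negbin`` — ``d = 1 + NegBin(shape r, prob p)``, variance
  ``m + m^2/r`` around the unshifted mean ``m``;
* ``shifted-binomial`` — ``d = 1 + Binomial(n, p)`` (bounded support).

Model likelihoods truncate and renormalise the pmf on ``1..support_max``;
maximum-likelihood fits use the untruncated pmf (truncation mass is
negligible for the zone lengths seen in shoot data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

FAMILIES = ("point", "shifted-poisson", "shifted-negbin", "shifted-binomial")

_N_PARAMS = {
    "point": 1,
    "shifted-poisson": 1,
    "shifted-negbin": 2,
    "shifted-binomial": 2,
}


@dataclass
class OccupancyDist:
    """Distribution of a zone's length in nodes (support d >= 1)."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown occupancy family {self.family!r}")
        self.params = {k: float(v) for k, v in self.params.items()}

    # ------------------------------------------------------------------ #
    @classmethod
    def point(cls, value: int) -> "OccupancyDist":
        return cls("point", {"value": int(value)})

    @classmethod
    def shifted_poisson(cls, mean: float) -> "OccupancyDist":
        """Shifted Poisson with total (shifted) mean ``mean`` >= 1."""
        if mean < 1.0:
            raise ValueError("shifted mean must be >= 1")
        return cls("shifted-poisson", {"mu": mean - 1.0})

    @classmethod
    def shifted_negbin(cls, mean: float, shape: float) -> "OccupancyDist":
        """Shifted negative binomial with shifted mean ``mean`` and shape
        (dispersion) ``r = shape``; larger shape is closer to Poisson."""
        if mean <= 1.0:
            raise ValueError("shifted mean must be > 1 for a negbin")
        mu = mean - 1.0
        p = shape / (shape + mu)
        return cls("shifted-negbin", {"r": shape, "p": p})

    @classmethod
    def shifted_binomial(cls, n: int, p: float) -> "OccupancyDist":
        return cls("shifted-binomial", {"n": int(n), "p": float(p)})

    # ------------------------------------------------------------------ #
    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.family]

    def mean(self) -> float:
        f, q = self.family, self.params
        if f == "point":
            return q["value"]
        if f == "shifted-poisson":
            return 1.0 + q["mu"]
        if f == "shifted-negbin":
            return 1.0 + q["r"] * (1.0 - q["p"]) / q["p"]
        return 1.0 + q["n"] * q["p"]

    def _rv(self):
        """Frozen scipy distribution of the unshifted count d - 1."""
        f, q = self.family, self.params
        if f == "shifted-poisson":
            return stats.poisson(q["mu"])
        if f == "shifted-negbin":
            return stats.nbinom(q["r"], q["p"])
        if f == "shifted-binomial":
            return stats.binom(int(q["n"]), q["p"])
        raise AssertionError(f)

    def log_pmf_vector(self, dmax: int) -> np.ndarray:
        """Log pmf over d = 1..dmax, renormalised on the truncated support."""
        if dmax < 1:
            raise ValueError("dmax must be >= 1")
        if self.family == "point":
            v = int(self.params["value"])
            out = np.full(dmax, -np.inf)
            if 1 <= v <= dmax:
                out[v - 1] = 0.0
            else:
                raise ValueError(
                    f"point occupancy at {v} outside truncated support 1..{dmax}"
                )
            return out
        logp = self._rv().logpmf(np.arange(dmax))
        with np.errstate(divide="ignore"):
            from scipy.special import logsumexp

            norm = logsumexp(logp)
        if not np.isfinite(norm):
            raise ValueError("occupancy has no mass on 1..dmax")
        return logp - norm

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        f, q = self.family, self.params
        if f == "point":
            return np.full(size, int(q["value"]), dtype=np.int64)
        if f == "shifted-poisson":
            return 1 + rng.poisson(q["mu"], size=size)
        if f == "shifted-negbin":
            return 1 + rng.negative_binomial(q["r"], q["p"], size=size)
        return 1 + rng.binomial(int(q["n"]), q["p"], size=size)

    def loglik(self, durations: np.ndarray) -> float:
        d = np.asarray(durations, dtype=np.int64)
        if self.family == "point":
            return 0.0 if np.all(d == int(self.params["value"])) else -np.inf
        return float(self._rv().logpmf(d - 1).sum())


# ---------------------------------------------------------------------- #
# maximum-likelihood fits per family
# ---------------------------------------------------------------------- #

def _fit_poisson(y: np.ndarray, w: np.ndarray) -> OccupancyDist:
    mu = max(float(np.average(y, weights=w)), 1e-6)
    return OccupancyDist("shifted-poisson", {"mu": mu})


def _negbin_logpmf(y, r, p):
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(p) + y * np.log1p(-p)
    )


def _fit_negbin(y: np.ndarray, w: np.ndarray) -> OccupancyDist:
    ybar = float(np.average(y, weights=w))
    ybar = max(ybar, 1e-6)

    def nll(logr: float) -> float:
        r = np.exp(logr)
        p = r / (r + ybar)  # profile MLE of p given r
        return -float(np.sum(w * _negbin_logpmf(y, r, p)))

    res = optimize.minimize_scalar(nll, bounds=(-6.0, 12.0), method="bounded")
    r = float(np.exp(res.x))
    return OccupancyDist("shifted-negbin", {"r": r, "p": r / (r + ybar)})


def _fit_binomial(y: np.ndarray, w: np.ndarray) -> OccupancyDist:
    ymax = int(np.max(y))
    ybar = float(np.average(y, weights=w))
    best, best_ll = None, -np.inf
    for n in range(max(ymax, 1), max(ymax, 1) + 31):
        p = min(max(ybar / n, 1e-9), 1 - 1e-9)
        ll = float(np.sum(w * stats.binom.logpmf(y, n, p)))
        if ll > best_ll + 1e-12:
            best, best_ll = OccupancyDist("shifted-binomial", {"n": n, "p": p}), ll
    return best


_FITTERS = {
    "shifted-poisson": _fit_poisson,
    "shifted-negbin": _fit_negbin,
    "shifted-binomial": _fit_binomial,
}


def fit_family(durations: Sequence[int], family: str,
               weights: Sequence[float] | None = None) -> OccupancyDist:
    """Weighted ML fit of one family to observed/expected zone lengths."""
    d = np.asarray(durations, dtype=np.float64)
    if np.any(d < 1):
        raise ValueError("durations must be >= 1")
    w = np.ones_like(d) if weights is None else np.asarray(weights, float)
    keep = w > 0
    d, w = d[keep], w[keep]
    if d.size == 0:
        raise ValueError("no durations with positive weight")
    if family == "point":
        # weighted mode
        vals, idx = np.unique(d, return_inverse=True)
        return OccupancyDist.point(int(vals[np.argmax(np.bincount(idx, w))]))
    y = d - 1.0
    if np.allclose(y, y[0]):
        if family == "shifted-binomial":
            n = max(int(y[0]), 1)
            return OccupancyDist("shifted-binomial", {"n": n, "p": min(y[0] / n, 1 - 1e-9)})
        if family == "shifted-negbin":
            return OccupancyDist("shifted-negbin", {"r": 1e4, "p": 1e4 / (1e4 + max(y[0], 1e-6))})
        return _fit_poisson(y, w)
    return _FITTERS[family](y, w)


def select_occupancy_family(durations: Sequence[int]) -> OccupancyDist:
    """Pick the best family by BIC (ties go to the simpler family).

    Degenerate input (all durations equal) short-circuits to a point mass.
    """
    d = np.asarray(durations, dtype=np.int64)
    if d.size < 5:
        raise ValueError("need at least 5 durations to select a family")
    if np.any(d < 1):
        raise ValueError("durations must be >= 1")
    if np.all(d == d[0]):
        return OccupancyDist.point(int(d[0]))
    n = d.size
    candidates = []
    for fam in ("shifted-poisson", "shifted-negbin", "shifted-binomial"):
        dist = fit_family(d, fam)
        bic = -2.0 * dist.loglik(d) + dist.n_params * np.log(n)
        candidates.append((bic, dist.n_params, fam, dist))
    candidates.sort(key=lambda c: (round(c[0], 9), c[1]))
    return candidates[0][3]
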