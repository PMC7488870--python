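"""Synthetic study generator with known ground truth.

Emulates one season of a high-density 'Fuji' orchard experiment: 227-odd
shoots measured weekly for length, then scored node-by-node for axillary
bud fates the following year.  Every shoot draws

1. a category — 71% monocyclic (one growth unit) vs 29% bicyclic, with
   sub-mixes over growth-duration (GD) and growth-period (GP) classes taken
   from the published cohort composition;
2. a weekly growth trajectory — near-linear extension from a start date
   (spring cohort centred on April 30, post-pruning cohort on June 26)
   until a stop chosen so the 0.5 cm / two-week rule detects cessation at
   start + GD, with Gaussian measurement noise (sd 0.3 cm); bicyclic shoots
   produce a double-sigmoid with an intermediate plateau;
3. a bud-fate sequence from the category's ground-truth hidden semi-Markov
   chain, whose zone visit probabilities follow the published occurrence
   rows and whose emission mixtures are invented defaults consistent with
   the verbal zone descriptions (each zone carries a clear majority of its
   characteristic lateral type so that zones remain statistically
   identifiable).

All draws are reproducible from a single seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .field_data import (
    ONE_GU, TWO_GUS, GD_SHORT, GD_MEDIUM, GD_LONG, GP_EARLY, GP_LATE,
    BranchingSequence, GrowthObservation, ShootCategory,
    ShootGrowthSeries, write_growth_records, write_sequences,
)
from .hsmm import EmissionDist, HSMMSpec, OccupancyDist, simulate

SEASON_END = dt.date(2016, 11, 15)


# ---------------------------------------------------------------------- #
# ground-truth hidden semi-Markov chains
# ---------------------------------------------------------------------- #

def monocyclic_spec(visit_s1: float, visit_s2: float, both: float = 0.0,
                    s0_mean: float = 7.0, s1_mean: float = 3.9,
                    s2_mean: float = 3.0, name: str = "") -> HSMMSpec:
    """3+1-state generator with prescribed zone visit probabilities.

    ``visit_s1``/``visit_s2`` are the marginal probabilities that a shoot
    possesses the diffuse floral (S1) and acrotonic vegetative (S2) zones;
    ``both`` the probability of possessing both (0 = mutually exclusive).
    """
    if both > min(visit_s1, visit_s2) + 1e-12:
        raise ConfigError("joint visit probability exceeds a marginal")
    p01 = visit_s1
    p12 = both / visit_s1 if visit_s1 > 0 else 0.0
    rest = 1.0 - visit_s1
    p02 = (visit_s2 - both) / rest if rest > 0 else 0.0
    trans = np.array([
        [0.0, p01, (1 - p01) * p02, (1 - p01) * (1 - p02)],
        [0.0, 0.0, p12, 1 - p12],
        [0.0, 0.0, 0.0, 1.0],
    ])
    occ = [OccupancyDist.shifted_poisson(s0_mean),
           OccupancyDist.shifted_negbin(s1_mean, 2.0),
           OccupancyDist.shifted_poisson(s2_mean)]
    emis = [
        EmissionDist.delta(0),
        # diffuse floral: latent buds with a marked floral component
        EmissionDist.from_dict({0: 0.45, 3: 0.45, 4: 0.10}, mask=[0, 1, 2, 3, 4]),
        # acrotonic vegetative: mostly long laterals, some short/latent
        EmissionDist.from_dict({0: 0.15, 1: 0.10, 2: 0.60, 3: 0.05, 4: 0.10},
                               mask=[0, 1, 2, 3, 4]),
    ]
    return HSMMSpec(np.array([1.0, 0.0, 0.0]), trans, occ, emis,
                    state_names=["S0", "S1", "S2"], name=name)


#: default emission mixtures of the 7-state model's free zones
_L_EMISSIONS = {
    1: {0: 0.45, 3: 0.45, 4: 0.10},            # L1 diffuse floral
    4: {0: 0.25, 1: 0.60, 2: 0.05, 4: 0.10},   # L4 short shoot zone
    5: {0: 0.10, 1: 0.05, 3: 0.70, 4: 0.15},   # L5 floral zone
    6: {0: 0.15, 1: 0.10, 2: 0.65, 4: 0.10},   # L6 acrotonic vegetative
}


def combined_spec(visit_l1: float, visit_l4: float, visit_l5: float,
                  visit_l6: float, bicyclic: bool,
                  occ_means=(7.0, 12.0, 2.0, 5.0, 4.0, 3.0, 4.0),
                  emissions: dict | None = None,
                  occupancy_family: str = "negbin",
                  name: str = "") -> HSMMSpec:
    """7+1-state generator with prescribed marginal zone visit probabilities.

    The post-cessation zones L4/L5/L6 are visited independently with the
    given marginals (a left-to-right chain realises any such marginals).
    ``bicyclic`` routes paths through the bud-scar cessation zone L2 and the
    second-GU latent zone L3; monocyclic long-GD shoots bypass L2.
    """
    S = 7
    trans = np.zeros((S, S + 1))
    trans[2, 3] = 1.0  # scar zone always exits to the second-GU latent zone
    if bicyclic:
        trans[0, 1], trans[0, 2] = visit_l1, 1 - visit_l1
        trans[1, 2] = 1.0
    else:
        if abs(visit_l1 - 1.0) > 1e-9:
            raise ConfigError("monocyclic long-GD shoots always possess L1")
        trans[0, 1] = 1.0
        trans[1, 3] = 1.0  # bypass the scar zone (unreachable for one-GU)
    v4, v5, v6 = visit_l4, visit_l5, visit_l6
    trans[3, 4] = v4
    trans[3, 5] = (1 - v4) * v5
    trans[3, 6] = (1 - v4) * (1 - v5) * v6
    trans[3, 7] = (1 - v4) * (1 - v5) * (1 - v6)
    trans[4, 5] = v5
    trans[4, 6] = (1 - v5) * v6
    trans[4, 7] = (1 - v5) * (1 - v6)
    trans[5, 6] = v6
    trans[5, 7] = 1 - v6
    trans[6, 7] = 1.0
    occ = []
    for j, m in enumerate(occ_means):
        if occupancy_family == "poisson" or j in (0, 2, 3) or m <= 1.2:
            occ.append(OccupancyDist.shifted_poisson(max(m, 1.0)))
        else:
            occ.append(OccupancyDist.shifted_negbin(m, 2.0))
    mix = dict(_L_EMISSIONS)
    if emissions:
        mix.update(emissions)
    free_mask = [0, 1, 2, 3, 4]
    emis = [
        EmissionDist.delta(0),
        EmissionDist.from_dict(mix[1], mask=free_mask),
        EmissionDist.delta(5),
        EmissionDist.delta(0),
        EmissionDist.from_dict(mix[4], mask=free_mask),
        EmissionDist.from_dict(mix[5], mask=free_mask),
        EmissionDist.from_dict(mix[6], mask=free_mask),
    ]
    init = np.zeros(S)
    init[0] = 1.0
    return HSMMSpec(init, trans, occ, emis,
                    state_names=[f"L{i}" for i in range(S)], name=name)


# ---------------------------------------------------------------------- #
# ground truth container
# ---------------------------------------------------------------------- #

@dataclass
class GrowthParams:
    """Trajectory parameters of one cohort (units: cm, cm/week, days)."""

    start_mean: dt.date
    start_sd_days: float = 6.0
    rate_mean: float = 3.0
    rate_sd: float = 0.5
    noise_sd: float = 0.3
    plateau_rate: float = 0.05


@dataclass
class GroundTruth:
    """Complete generating description of a synthetic study."""

    # cohort composition (published percentages)
    p_one_gu: float = 0.71
    one_gu_gd_mix: dict = field(default_factory=lambda: {
        GD_SHORT: 0.65, GD_MEDIUM: 0.28, GD_LONG: 0.07})
    one_gu_gp_late: dict = field(default_factory=lambda: {
        GD_SHORT: 0.50, GD_MEDIUM: 0.15, GD_LONG: 0.0})
    gu1_gd_long: float = 0.67
    gu1_gp_late_by_gd: dict = field(default_factory=lambda: {
        GD_SHORT: 0.32, GD_LONG: 0.0})
    gu2_gd_long: float = 0.58
    gu2_gp_late_by_gd: dict = field(default_factory=lambda: {
        GD_SHORT: 0.90, GD_LONG: 0.61})
    # GD class target distributions (mean, sd, lo, hi), days; invented,
    # kept clear of the 30/90-day boundaries so noisy detection stays in
    # class.  "long-bicyclic" is the long class of a bicyclic GU (> 30 d
    # threshold, but bounded by the within-season window of that GU).
    gd_days: dict = field(default_factory=lambda: {
        GD_SHORT: (17.0, 2.0, 14.0, 22.0),
        GD_MEDIUM: (55.0, 10.0, 38.0, 78.0),
        GD_LONG: (110.0, 8.0, 96.0, 130.0),
        "long-bicyclic": (55.0, 8.0, 36.0, 70.0),
    })
    # growth trajectories per start cohort
    spring: GrowthParams = field(default_factory=lambda: GrowthParams(dt.date(2016, 4, 30)))
    late: GrowthParams = field(default_factory=lambda: GrowthParams(dt.date(2016, 6, 26)))
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.p_one_gu <= 1:
            raise ConfigError("p_one_gu must be a probability")
        if abs(sum(self.one_gu_gd_mix.values()) - 1) > 1e-9:
            raise ConfigError("one-GU GD mix must sum to 1")

    # ---- generating chains (published occurrence rows) ---- #
    def sequence_spec(self, cyclicity: str, gd_class: str) -> HSMMSpec:
        if cyclicity == ONE_GU and gd_class == GD_SHORT:
            return monocyclic_spec(0.26, 0.09, both=0.0, s1_mean=3.9,
                                   name="one-GU-short")
        if cyclicity == ONE_GU and gd_class == GD_MEDIUM:
            return monocyclic_spec(0.71, 0.23, both=0.13, s1_mean=13.4,
                                   s2_mean=5.0, name="one-GU-medium")
        if cyclicity == ONE_GU and gd_class == GD_LONG:
            return combined_spec(1.0, 0.64, 0.55, 0.82, bicyclic=False,
                                 occ_means=(7.0, 16.0, 2.0, 5.0, 4.0, 3.0, 4.0),
                                 name="one-GU-long")
        return combined_spec(0.65, 0.62, 0.47, 0.73, bicyclic=True,
                             name="two-GUs")

    def to_dict(self) -> dict:
        return {
            "p_one_gu": self.p_one_gu,
            "one_gu_gd_mix": dict(self.one_gu_gd_mix),
            "one_gu_gp_late": dict(self.one_gu_gp_late),
            "gu1_gd_long": self.gu1_gd_long,
            "gu1_gp_late_by_gd": dict(self.gu1_gp_late_by_gd),
            "gu2_gd_long": self.gu2_gd_long,
            "gu2_gp_late_by_gd": dict(self.gu2_gp_late_by_gd),
            "gd_days": {k: list(v) for k, v in self.gd_days.items()},
            "noise_sd": self.noise_sd,
            "specs": {
                "one-GU-short": self.sequence_spec(ONE_GU, GD_SHORT).to_dict(),
                "one-GU-medium": self.sequence_spec(ONE_GU, GD_MEDIUM).to_dict(),
                "one-GU-long": self.sequence_spec(ONE_GU, GD_LONG).to_dict(),
                "two-GUs": self.sequence_spec(TWO_GUS, "").to_dict(),
            },
        }


def default_ground_truth() -> GroundTruth:
    """The study conditions: published cohort mix, start dates and zone
    occurrence rows; invented (documented) trajectory and emission defaults."""
    return GroundTruth()


# ---------------------------------------------------------------------- #
# growth trajectories
# ---------------------------------------------------------------------- #

def _weekly_dates(anchor: dt.date, first: dt.date, last: dt.date) -> list:
    """Weekly grid through ``anchor`` covering [first, last]."""
    k0 = -((anchor - first).days // 7)
    dates = []
    k = k0
    while True:
        d = anchor + dt.timedelta(days=7 * k)
        if d > last:
            break
        if d >= first:
            dates.append(d)
        k += 1
    return dates


def _draw_start(rng, params: GrowthParams, latest: dt.date | None = None,
                earliest: dt.date | None = None) -> dt.date:
    for _ in range(200):
        offs = rng.normal(0.0, params.start_sd_days)
        d = params.start_mean + dt.timedelta(days=round(offs))
        if (latest is None or d <= latest) and (earliest is None or d >= earliest):
            return d
    return latest or params.start_mean


def _draw_gd(rng, spec_tuple) -> float:
    mean, sd, lo, hi = spec_tuple
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def simulate_growth_series(shoot_id: str, category: ShootCategory,
                           ground_truth: GroundTruth, seed=None) -> ShootGrowthSeries:
    """Weekly length series whose detected start/cessation dates reproduce
    the drawn category under the categorisation rules.

    The trajectory is piecewise linear in expectation: ~1 cm two weeks
    before the start, 6 cm at the start observation, constant extension
    until ``start + GD - window``, then a slow plateau drift, so the
    trailing two-week rule fires one window after true growth stop — i.e.
    at ``start + GD``.  Bicyclic shoots hold the plateau for at least three
    weeks and then jump past the second-GU start criterion (+5 cm over the
    cessation length) exactly at the second start date, which is snapped to
    the weekly observation grid.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gt = ground_truth
    gus = category.gu_classes
    window = 14  # categorisation default; trajectories are built for it
    bicyclic = category.cyclicity == TWO_GUS

    gd1_class, gp1_class = gus[0]
    if gp1_class == GP_EARLY:
        if bicyclic:
            start1 = _draw_start(rng, GrowthParams(dt.date(2016, 4, 25), 5.0),
                                 latest=dt.date(2016, 5, 8),
                                 earliest=dt.date(2016, 4, 10))
        else:
            start1 = _draw_start(rng, gt.spring, latest=dt.date(2016, 6, 1))
    else:
        if bicyclic:  # late first GU still leaves room for a second GU
            start1 = _draw_start(rng, GrowthParams(dt.date(2016, 6, 8), 2.0),
                                 latest=dt.date(2016, 6, 12),
                                 earliest=dt.date(2016, 6, 4))
        else:
            start1 = _draw_start(rng, gt.late, earliest=dt.date(2016, 6, 8))
    key1 = "long-bicyclic" if (bicyclic and gd1_class == GD_LONG) else gd1_class
    gd1 = _draw_gd(rng, gt.gd_days[key1])
    rate1 = max(rng.normal(gt.spring.rate_mean, gt.spring.rate_sd), 1.5)

    phases = None
    if bicyclic:
        gd2_class, gp2_class = gus[1]
        if gp2_class == GP_EARLY:
            # second GU must start by mid-July: bound the first GD so the
            # inter-GU plateau (>= 3 weeks) still fits
            cap1 = (dt.date(2016, 6, 20) - start1).days + window
            gd1 = min(gd1, float(cap1))
        stop1 = start1 + dt.timedelta(days=max(round(gd1) - window, 0))
        lo2 = stop1 + dt.timedelta(days=window + 7)

        def snap(d: dt.date) -> dt.date:
            # round up to the weekly observation grid anchored at start1
            return start1 + dt.timedelta(days=7 * int(np.ceil((d - start1).days / 7)))

        if gp2_class == GP_EARLY:
            raw = _draw_start(rng, GrowthParams(dt.date(2016, 7, 1), 5.0),
                              latest=dt.date(2016, 7, 11),
                              earliest=max(lo2, dt.date(2016, 6, 10)))
            start2 = snap(max(raw, lo2))
            if start2 > dt.date(2016, 7, 11):
                start2 = snap(lo2)
        else:
            raw = _draw_start(rng, GrowthParams(dt.date(2016, 7, 28), 5.0),
                              latest=dt.date(2016, 8, 24),
                              earliest=max(lo2, dt.date(2016, 7, 20)))
            start2 = snap(max(raw, lo2, dt.date(2016, 7, 20)))
        key2 = "long-bicyclic" if gd2_class == GD_LONG else gd2_class
        gd2 = _draw_gd(rng, gt.gd_days[key2])
        gd2 = min(gd2, float((SEASON_END - start2).days))
        stop2 = start2 + dt.timedelta(days=max(round(gd2) - window, 0))
        rate2 = max(rng.normal(gt.spring.rate_mean, gt.spring.rate_sd), 1.5)
        phases = [(start1, stop1, rate1), (start2, stop2, rate2)]
    else:
        stop1 = start1 + dt.timedelta(days=max(round(gd1) - window, 0))
        phases = [(start1, stop1, rate1)]

    first_obs = start1 - dt.timedelta(days=14)
    dates = _weekly_dates(start1, first_obs, SEASON_END)
    drift = gt.spring.plateau_rate / 7.0  # cm per day on a plateau

    def base_length(d: dt.date) -> float:
        # pre-start ramp reaching 6 cm at the start observation
        if d < start1:
            return max(6.0 - 0.36 * (start1 - d).days, 0.5)
        length = 6.0
        prev_stop = start1
        for k, (s, stop, rate) in enumerate(phases):
            if k > 0:
                length += drift * (min(d, s) - prev_stop).days
                if d < s:
                    return length
                length += 5.5  # jump past the +5 cm second-start criterion
            length += rate / 7.0 * max((min(d, stop) - s).days, 0)
            if d <= stop:
                return length
            prev_stop = stop
        return length + drift * (d - prev_stop).days

    obs = []
    prev = 0.0
    for d in dates:
        noise = rng.normal(0.0, gt.noise_sd)
        # a re-measured length can jitter slightly below the previous
        # record but a shoot never truly shrinks
        value = max(base_length(d) + noise, 0.1, prev - 0.4)
        obs.append(GrowthObservation(shoot_id, d, value))
        prev = value
    return ShootGrowthSeries(shoot_id, obs)


# ---------------------------------------------------------------------- #
# category and study simulation
# ---------------------------------------------------------------------- #

def draw_category(rng, gt: GroundTruth) -> ShootCategory:
    if rng.random() < gt.p_one_gu:
        gd = rng.choice(list(gt.one_gu_gd_mix), p=list(gt.one_gu_gd_mix.values()))
        gp = GP_LATE if rng.random() < gt.one_gu_gp_late[gd] else GP_EARLY
        return ShootCategory(ONE_GU, ((gd, gp),))
    gd1 = GD_LONG if rng.random() < gt.gu1_gd_long else GD_SHORT
    gp1 = GP_LATE if rng.random() < gt.gu1_gp_late_by_gd[gd1] else GP_EARLY
    gd2 = GD_LONG if rng.random() < gt.gu2_gd_long else GD_SHORT
    gp2 = GP_LATE if rng.random() < gt.gu2_gp_late_by_gd[gd2] else GP_EARLY
    return ShootCategory(TWO_GUS, ((gd1, gp1), (gd2, gp2)))


@dataclass
class StudyTruth:
    """Per-shoot generating record for recovery scoring."""

    categories: dict            # shoot_id -> ShootCategory
    spec_names: dict            # shoot_id -> generating spec name
    true_paths: dict            # shoot_id -> per-node generating states
    ground_truth: GroundTruth


def simulate_study(n_shoots: int, ground_truth: GroundTruth | None = None,
                   seed: int | None = 0, out_dir=None):
    """Draw a complete paired study.

    Returns ``(series_list, sequence_list, truth)``; when ``out_dir`` is
    given also writes ``growth.csv``, ``sequences.tsv`` and ``truth.yaml``
    in the exact dialects the readers expect.
    """
    if n_shoots < 1:
        raise ConfigError("n_shoots must be >= 1")
    gt = ground_truth or default_ground_truth()
    rng = np.random.default_rng(seed)
    series_list, seq_list = [], []
    truth = StudyTruth({}, {}, {}, gt)
    for i in range(n_shoots):
        sid = f"shoot{i+1:04d}"
        cat = draw_category(rng, gt)
        series = simulate_growth_series(sid, cat, gt, seed=rng)
        spec = gt.sequence_spec(cat.cyclicity, cat.gu_classes[0][0])
        seqs, paths = simulate(spec, 1, seed=rng)
        seq_list.append(BranchingSequence(sid, seqs[0], cat))
        series_list.append(series)
        truth.categories[sid] = cat
        truth.spec_names[sid] = spec.name
        truth.true_paths[sid] = paths[0]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_growth_records(series_list, out / "growth.csv")
        write_sequences(seq_list, out / "sequences.tsv")
        doc = {
            "seed": seed,
            "n_shoots": n_shoots,
            "ground_truth": gt.to_dict(),
            "categories": {sid: c.label() for sid, c in truth.categories.items()},
            "specs": dict(truth.spec_names),
        }
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)
    return series_list, seq_list, truth
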