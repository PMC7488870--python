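"""Growth records, bud-fate sequences, and shoot categorisation.

Weekly cumulative-length measurements drive the grouping of shoots:

* growth *cessation* — the trailing gain over the nearest observation at
  least ``cessation_window_days`` earlier falls below ``cessation_delta_cm``
  (default: less than 0.5 cm over two weeks);
* *start date* — the first observation at which the shoot reaches
  ``start_length_cm`` (5 cm); a second growth unit (GU) starts when the
  length exceeds the first cessation length by the same criterion;
* *growth duration* (GD) — cessation date minus start date, classified
  short (< 30 d) / medium (30–90 d, monocyclic only) / long (> 90 d);
* *growth period* (GP) — early iff the start date falls on or before a
  calendar threshold (June 3 for first/only GUs, July 18 for second GUs).

Bud-fate sequences code each node base-to-tip with symbols 0 latent,
1 short vegetative shoot, 2 long vegetative shoot, 3 bourse with short
bourse shoot, 4 bourse with long bourse shoot, 5 bud scar (cessation
marker, bicyclic shoots only).
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import ConfigError, DataError

logger = logging.getLogger("shootzones")

SHRINK_TOLERANCE_CM = 1.0  # measured length may jitter down, not truly shrink

GD_SHORT, GD_MEDIUM, GD_LONG = "short", "medium", "long"
GP_EARLY, GP_LATE = "early", "late"
ONE_GU, TWO_GUS = "one-GU", "two-GUs"


def _parse_date(s: str) -> dt.date:
    try:
        return dt.date.fromisoformat(s)
    except ValueError as exc:
        raise DataError(f"unparseable date {s!r}") from exc


# ---------------------------------------------------------------------- #
# configuration
# ---------------------------------------------------------------------- #

@dataclass
class CategoryConfig:
    """Thresholds of the shoot-categorisation rules."""

    cessation_delta_cm: float = 0.5
    cessation_window_days: int = 14
    start_length_cm: float = 5.0
    gd_thresholds_one_gu_days: tuple = (30, 90)
    gd_threshold_two_gu_days: int = 30
    gp_threshold_first: dt.date = dt.date(2016, 6, 3)
    gp_threshold_second: dt.date = dt.date(2016, 7, 18)

    def __post_init__(self) -> None:
        for d in ("gp_threshold_first", "gp_threshold_second"):
            v = getattr(self, d)
            if isinstance(v, str):
                setattr(self, d, _parse_date(v))
        lo, hi = self.gd_thresholds_one_gu_days
        if not (0 < lo < hi):
            raise ConfigError("one-GU GD thresholds must be positive and increasing")
        if min(self.cessation_delta_cm, self.cessation_window_days,
               self.start_length_cm, self.gd_threshold_two_gu_days) <= 0:
            raise ConfigError("thresholds must be positive")

    def to_dict(self) -> dict:
        return {
            "cessation_delta_cm": self.cessation_delta_cm,
            "cessation_window_days": self.cessation_window_days,
            "start_length_cm": self.start_length_cm,
            "gd_thresholds_one_gu_days": list(self.gd_thresholds_one_gu_days),
            "gd_threshold_two_gu_days": self.gd_threshold_two_gu_days,
            "gp_threshold_first": self.gp_threshold_first.isoformat(),
            "gp_threshold_second": self.gp_threshold_second.isoformat(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryConfig":
        d = dict(d)
        if "gd_thresholds_one_gu_days" in d:
            d["gd_thresholds_one_gu_days"] = tuple(d["gd_thresholds_one_gu_days"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CategoryConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------- #
# growth series
# ---------------------------------------------------------------------- #

@dataclass
class GrowthObservation:
    shoot_id: str
    date: dt.date
    length: float  # cumulative shoot length, cm

    def __post_init__(self) -> None:
        if isinstance(self.date, str):
            self.date = _parse_date(self.date)
        if self.length < 0:
            raise DataError(f"negative length for shoot {self.shoot_id}")


@dataclass
class ShootGrowthSeries:
    shoot_id: str
    observations: list

    def __post_init__(self) -> None:
        obs = sorted(self.observations, key=lambda o: o.date)
        if len(obs) < 2:
            raise DataError(f"shoot {self.shoot_id}: need at least 2 observations")
        for a, b in zip(obs, obs[1:]):
            if a.date == b.date:
                raise DataError(f"shoot {self.shoot_id}: duplicate date {a.date}")
            if b.length < a.length - SHRINK_TOLERANCE_CM:
                raise DataError(
                    f"shoot {self.shoot_id}: length shrinks by more than "
                    f"{SHRINK_TOLERANCE_CM} cm at {b.date}")
        self.observations = obs

    @property
    def dates(self) -> list:
        return [o.date for o in self.observations]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([o.length for o in self.observations])


@dataclass
class ParseReport:
    rows_read: int = 0
    rows_rejected: int = 0
    errors: list = field(default_factory=list)


def read_growth_records(path) -> tuple[list, ParseReport]:
    """Read a ``shoot_id,date,length_cm`` CSV into one series per shoot.

    Rows that violate row-level invariants are rejected and reported with
    their line number; shoots left with fewer than 2 valid rows are dropped
    (also reported).
    """
    report = ParseReport()
    rows: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"shoot_id", "date", "length_cm"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise DataError(f"growth CSV must have columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            report.rows_read += 1
            sid = (row["shoot_id"] or "").strip()
            try:
                if not sid:
                    raise DataError("empty shoot_id")
                date = _parse_date(row["date"].strip())
                length = float(row["length_cm"])
                if length < 0:
                    raise DataError("negative length")
                per = rows.setdefault(sid, {})
                if date in per:
                    raise DataError(f"duplicate (shoot {sid}, date {date})")
                per[date] = length
            except (DataError, ValueError) as exc:
                report.rows_rejected += 1
                report.errors.append(f"line {lineno}: {exc}")
    if report.rows_read == 0:
        logger.warning("growth CSV %s contains no data rows", path)
    series = []
    for sid, per in rows.items():
        obs = [GrowthObservation(sid, d, l) for d, l in sorted(per.items())]
        try:
            series.append(ShootGrowthSeries(sid, obs))
        except DataError as exc:
            report.rows_rejected += len(obs)
            report.errors.append(str(exc))
    return series, report


def write_growth_records(series: Iterable[ShootGrowthSeries], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["shoot_id", "date", "length_cm"])
        for s in series:
            for o in s.observations:
                w.writerow([s.shoot_id, o.date.isoformat(), f"{o.length:.2f}"])


# ---------------------------------------------------------------------- #
# cessation / start / GU spans
# ---------------------------------------------------------------------- #

def detect_cessations(series: ShootGrowthSeries, cfg: CategoryConfig) -> list | None:
    """Dates at which growth stagnation episodes begin.

    An observation qualifies when the gain over the nearest observation at
    least ``cessation_window_days`` earlier is below ``cessation_delta_cm``;
    a maximal run of consecutive qualifying observations is one episode and
    its earliest date is reported.  Returns ``None`` (no assessment) when
    the series is shorter than the window, ``[]`` when growth never stops.
    """
    dates = series.dates
    lengths = series.lengths
    span = (dates[-1] - dates[0]).days
    if span < cfg.cessation_window_days:
        return None
    qualifies = []
    for k, d in enumerate(dates):
        ref = None
        for j in range(k - 1, -1, -1):
            if (d - dates[j]).days >= cfg.cessation_window_days:
                ref = j
                break
        qualifies.append(ref is not None and
                         lengths[k] - lengths[ref] < cfg.cessation_delta_cm)
    episodes = []
    in_episode = False
    for k, q in enumerate(qualifies):
        if q and not in_episode:
            episodes.append(dates[k])
            in_episode = True
        elif not q:
            in_episode = False
    return episodes


def compute_start_date(series: ShootGrowthSeries, cfg: CategoryConfig,
                       after: dt.date | None = None,
                       baseline: float = 0.0) -> dt.date | None:
    """First observation date with length >= baseline + start criterion.

    For the primary GU ``baseline`` is 0; for a second GU pass the length at
    the first cessation and ``after`` that cessation date.  Returns ``None``
    when the criterion is never reached.
    """
    for o in series.observations:
        if after is not None and o.date <= after:
            continue
        if o.length >= baseline + cfg.start_length_cm:
            return o.date
    return None


@dataclass
class GUSpan:
    """One growth unit: start and cessation dates within the season."""

    index: int  # 1 or 2
    start_date: dt.date
    cessation_date: dt.date

    def __post_init__(self) -> None:
        if self.index not in (1, 2):
            raise DataError("GU index must be 1 or 2")
        if self.cessation_date < self.start_date:
            raise DataError("cessation before start")

    @property
    def gd_days(self) -> int:
        return (self.cessation_date - self.start_date).days


@dataclass
class ShootCategory:
    """Cyclicity plus per-GU growth-duration and growth-period classes."""

    cyclicity: str
    gu_classes: tuple  # ((gd_class, gp_class),) or two such pairs

    def __post_init__(self) -> None:
        self.gu_classes = tuple(tuple(p) for p in self.gu_classes)
        n = len(self.gu_classes)
        if self.cyclicity == ONE_GU and n != 1:
            raise DataError("one-GU shoot needs exactly one (gd, gp) pair")
        if self.cyclicity == TWO_GUS and n != 2:
            raise DataError("two-GUs shoot needs one (gd, gp) pair per GU")
        if self.cyclicity not in (ONE_GU, TWO_GUS):
            raise DataError(f"unknown cyclicity {self.cyclicity!r}")
        for i, (gd, gp) in enumerate(self.gu_classes):
            if gp not in (GP_EARLY, GP_LATE):
                raise DataError(f"unknown gp_class {gp!r}")
            allowed = (GD_SHORT, GD_MEDIUM, GD_LONG) if self.cyclicity == ONE_GU \
                else (GD_SHORT, GD_LONG)
            if gd not in allowed:
                raise DataError(f"gd_class {gd!r} not valid for {self.cyclicity} GU{i+1}")

    @property
    def gd_class(self) -> str:
        return "+".join(gd for gd, _ in self.gu_classes)

    @property
    def gp_class(self) -> str:
        return "+".join(gp for _, gp in self.gu_classes)

    def label(self) -> str:
        return f"{self.cyclicity}|{self.gd_class}|{self.gp_class}"


def classify_shoot(spans: Sequence[GUSpan], cfg: CategoryConfig) -> ShootCategory:
    """Apply the GD/GP thresholds to 1 or 2 growth-unit spans.

    Boundary conventions: GD exactly 30 or 90 days is *medium* for a
    monocyclic shoot (the printed interval is closed); a start date exactly
    on the calendar threshold is *early*.
    """
    if not 1 <= len(spans) <= 2:
        raise DataError("a shoot has one or two growth units")
    spans = sorted(spans, key=lambda s: s.index)
    if len(spans) == 2:
        if spans[0].cessation_date > spans[1].start_date:
            raise DataError("GU spans overlap")
    if len(spans) == 1:
        gu = spans[0]
        lo, hi = cfg.gd_thresholds_one_gu_days
        if gu.gd_days < lo:
            gd = GD_SHORT
        elif gu.gd_days <= hi:
            gd = GD_MEDIUM
        else:
            gd = GD_LONG
        gp = GP_EARLY if gu.start_date <= cfg.gp_threshold_first else GP_LATE
        return ShootCategory(ONE_GU, ((gd, gp),))
    pairs = []
    for gu in spans:
        gd = GD_SHORT if gu.gd_days < cfg.gd_threshold_two_gu_days else GD_LONG
        thr = cfg.gp_threshold_first if gu.index == 1 else cfg.gp_threshold_second
        gp = GP_EARLY if gu.start_date <= thr else GP_LATE
        pairs.append((gd, gp))
    return ShootCategory(TWO_GUS, tuple(pairs))


@dataclass
class CategorizationOutcome:
    shoot_id: str
    category: ShootCategory | None
    spans: list
    exclusion_reason: str | None = None


def categorize_series(series: ShootGrowthSeries, cfg: CategoryConfig) -> CategorizationOutcome:
    """Full categorisation of one shoot, or a logged exclusion reason.

    A second GU is only opened when, after the first cessation, the shoot
    gains a further ``start_length_cm`` over the cessation length; smaller
    rebounds (measurement noise) leave the shoot monocyclic.
    """
    sid = series.shoot_id

    def excluded(reason: str) -> CategorizationOutcome:
        logger.info("shoot %s excluded: %s", sid, reason)
        return CategorizationOutcome(sid, None, [], reason)

    start1 = compute_start_date(series, cfg)
    if start1 is None:
        return excluded(f"never reached {cfg.start_length_cm} cm")
    episodes = detect_cessations(series, cfg)
    if episodes is None:
        return excluded("series shorter than the cessation window")
    cess1 = next((d for d in episodes if d >= start1), None)
    if cess1 is None:
        return excluded("no within-season growth cessation detected")
    len_at_cess1 = float(series.lengths[series.dates.index(cess1)])
    spans = [GUSpan(1, start1, cess1)]
    start2 = compute_start_date(series, cfg, after=cess1, baseline=len_at_cess1)
    if start2 is not None:
        cess2 = next((d for d in episodes if d >= start2), None)
        if cess2 is None:
            return excluded("second GU never ceased growth")
        spans.append(GUSpan(2, start2, cess2))
    try:
        cat = classify_shoot(spans, cfg)
    except DataError as exc:
        return excluded(str(exc))
    return CategorizationOutcome(sid, cat, spans)


# ---------------------------------------------------------------------- #
# bud-fate sequences
# ---------------------------------------------------------------------- #

ALPHABET = (0, 1, 2, 3, 4, 5)
SCAR = 5


@dataclass
class BranchingSequence:
    """Ordered bud-fate symbols for one shoot, base to tip."""

    shoot_id: str
    symbols: np.ndarray
    category: ShootCategory | None = None

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 1 or self.symbols.size < 1:
            raise DataError(f"shoot {self.shoot_id}: sequence must be non-empty")
        bad = np.flatnonzero((self.symbols < 0) | (self.symbols > 5))
        if bad.size:
            raise DataError(
                f"shoot {self.shoot_id}: invalid symbol at node {int(bad[0])}")
        scar = self.symbols == SCAR
        if scar.any():
            runs = np.flatnonzero(np.diff(scar.astype(int)) == 1).size + int(scar[0])
            if runs > 1:
                raise DataError(
                    f"shoot {self.shoot_id}: bud-scar symbols must form one contiguous run")
            if self.category is not None and self.category.cyclicity != TWO_GUS:
                raise DataError(
                    f"shoot {self.shoot_id}: bud-scar symbols only valid for two-GUs shoots")

    def __len__(self) -> int:
        return int(self.symbols.size)


def write_sequences(seqs: Iterable[BranchingSequence], path) -> None:
    """TSV: shoot_id, cyclicity, gd_class, gp_class, space-separated symbols."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["shoot_id", "cyclicity", "gd_class", "gp_class", "symbols"])
        for s in seqs:
            cat = s.category
            w.writerow([
                s.shoot_id,
                cat.cyclicity if cat else "",
                cat.gd_class if cat else "",
                cat.gp_class if cat else "",
                " ".join(str(int(v)) for v in s.symbols),
            ])


def read_sequences(path) -> list:
    """Inverse of :func:`write_sequences` (lossless round-trip)."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"shoot_id", "cyclicity", "gd_class", "gp_class", "symbols"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise DataError(f"sequence TSV must have columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                symbols = np.array([int(v) for v in row["symbols"].split()])
            except ValueError as exc:
                raise DataError(f"line {lineno}: bad symbol field") from exc
            cat = None
            if row["cyclicity"]:
                gds = row["gd_class"].split("+")
                gps = row["gp_class"].split("+")
                if len(gds) != len(gps):
                    raise DataError(f"line {lineno}: mismatched gd/gp classes")
                cat = ShootCategory(row["cyclicity"], tuple(zip(gds, gps)))
            try:
                out.append(BranchingSequence(row["shoot_id"], symbols, cat))
            except DataError as exc:
                raise DataError(f"line {lineno}: {exc}") from exc
    return out
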