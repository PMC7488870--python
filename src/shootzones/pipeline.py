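"""End-to-end orchestration: categorize -> split cohorts -> fit -> decode ->
zone analyses -> comparative statistics -> report.

Shoots are split into the two model cohorts the estimation requires
(a single chain over all categories segments poorly): monocyclic shoots
with short or medium growth duration (3+1-state model) versus monocyclic
long-GD plus bicyclic shoots (7+1-state model).  Every stage writes its
outputs under the run directory together with a content marker, so re-runs
with an unchanged configuration skip completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare as cmp
from . import zones as zn
from .errors import ConfigError, DataError
from .field_data import (
    ONE_GU, TWO_GUS, GD_SHORT, GD_MEDIUM,
    BranchingSequence, CategoryConfig, categorize_series,
    read_growth_records, read_sequences,
)
from .hsmm import (
    EMSettings, HSMMSpec, combined_template, fit_em, monocyclic_template,
    viterbi_decode,
)

logger = logging.getLogger("shootzones")

COHORT_A = "one-GU-short-medium"
COHORT_B = "one-GU-long-and-two-GUs"


@dataclass
class RunConfig:
    out_dir: str
    growth_csv: str | None = None
    sequences_tsv: str | None = None
    seed: int = 0
    min_cohort: int = 5
    category: CategoryConfig = field(default_factory=CategoryConfig)
    em: EMSettings = field(default_factory=EMSettings)

    def __post_init__(self) -> None:
        if self.growth_csv is None and self.sequences_tsv is None:
            raise ConfigError("need a growth CSV and/or a sequences TSV")

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "growth_csv": self.growth_csv and str(self.growth_csv),
            "sequences_tsv": self.sequences_tsv and str(self.sequences_tsv),
            "seed": self.seed,
            "min_cohort": self.min_cohort,
            "category": self.category.to_dict(),
            "em": {
                "n_restarts": self.em.n_restarts,
                "tol": self.em.tol,
                "max_iter": self.em.max_iter,
                "emission_floor": self.em.emission_floor,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "category" in d:
            d["category"] = CategoryConfig.from_dict(d["category"])
        if "em" in d:
            d["em"] = EMSettings(**d["em"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"bad run configuration: {exc}") from exc

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: not a mapping")
        return cls.from_dict(doc)


def _content_key(cfg: RunConfig, stage: str, extra: str = "") -> str:
    h = hashlib.sha256()
    h.update(json.dumps(cfg.to_dict(), sort_keys=True).encode())
    h.update(stage.encode())
    h.update(extra.encode())
    for p in (cfg.growth_csv, cfg.sequences_tsv):
        if p and Path(p).exists():
            h.update(Path(p).read_bytes())
    return h.hexdigest()


def _stage_done(out: Path, stage: str, key: str) -> bool:
    marker = out / f".{stage}.done"
    if marker.exists() and marker.read_text().strip() == key:
        logger.info("stage %s up to date; skipping", stage)
        return True
    return False


def _mark_done(out: Path, stage: str, key: str) -> None:
    (out / f".{stage}.done").write_text(key)


# ---------------------------------------------------------------------- #
# stages
# ---------------------------------------------------------------------- #

def stage_categorize(cfg: RunConfig) -> pd.DataFrame:
    """Classify every shoot from its growth series; write categories.tsv."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    key = _content_key(cfg, "categorize")
    path = out / "categories.tsv"
    if _stage_done(out, "categorize", key) and path.exists():
        return pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if cfg.growth_csv is None:
        raise ConfigError("categorize stage needs a growth CSV")
    series, report = read_growth_records(cfg.growth_csv)
    for err in report.errors:
        logger.warning("growth CSV: %s", err)
    rows = []
    for s in series:
        outcome = categorize_series(s, cfg.category)
        c = outcome.category
        rows.append({
            "shoot_id": s.shoot_id,
            "cyclicity": c.cyclicity if c else "",
            "gd_class": c.gd_class if c else "",
            "gp_class": c.gp_class if c else "",
            "excluded": outcome.exclusion_reason or "",
        })
    df = pd.DataFrame(rows).sort_values("shoot_id").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    _mark_done(out, "categorize", key)
    return df


def _attach_categories(seqs: list, categories: pd.DataFrame | None) -> list:
    if categories is None:
        return [s for s in seqs if s.category is not None]
    from .field_data import ShootCategory

    by_id = {r.shoot_id: r for r in categories.itertuples() if r.cyclicity}
    out = []
    for s in seqs:
        row = by_id.get(s.shoot_id)
        if row is not None:
            cat = ShootCategory(row.cyclicity,
                                tuple(zip(row.gd_class.split("+"),
                                          row.gp_class.split("+"))))
            try:
                out.append(BranchingSequence(s.shoot_id, s.symbols, cat))
            except DataError as exc:
                # growth-derived cyclicity conflicts with the bud-scar
                # evidence in the sequence itself; scars identify the
                # within-season cessation, so keep the sequence's category
                logger.warning("shoot %s: %s; keeping sequence category",
                               s.shoot_id, exc)
                if s.category is not None:
                    out.append(s)
        elif s.category is not None:
            out.append(s)
    return out


def split_cohorts(seqs: list) -> dict:
    """The two estimation cohorts used for the two chain models."""
    a, b = [], []
    for s in seqs:
        if s.category is None:
            continue
        if s.category.cyclicity == ONE_GU and \
                s.category.gd_class in (GD_SHORT, GD_MEDIUM):
            a.append(s)
        else:
            b.append(s)
    return {COHORT_A: a, COHORT_B: b}


def stage_fit(cfg: RunConfig, cohorts: dict) -> dict:
    """Fit one constrained chain per cohort (skipped below min_cohort)."""
    out = Path(cfg.out_dir)
    results = {}
    templates = {COHORT_A: monocyclic_template, COHORT_B: combined_template}
    for name, seqs in cohorts.items():
        model_path = out / f"model_{name}.yaml"
        key = _content_key(cfg, f"fit-{name}", extra=str(len(seqs)))
        if _stage_done(out, f"fit-{name}", key) and model_path.exists():
            results[name] = HSMMSpec.load(model_path)
            continue
        if len(seqs) < cfg.min_cohort:
            logger.warning("cohort %s has %d sequences (< %d); model skipped",
                           name, len(seqs), cfg.min_cohort)
            continue
        mean_len = float(np.mean([len(s) for s in seqs]))
        template = templates[name](mean_len)
        settings = EMSettings(n_restarts=cfg.em.n_restarts, tol=cfg.em.tol,
                              max_iter=cfg.em.max_iter, seed=cfg.seed,
                              emission_floor=cfg.em.emission_floor)
        res = fit_em(seqs, template, settings)
        res.spec.save(model_path)
        (out / f"model_{name}.txt").write_text(res.summary() + "\n")
        results[name] = res.spec
        _mark_done(out, f"fit-{name}", key)
    return results


def stage_decode(cfg: RunConfig, cohorts: dict, models: dict) -> dict:
    """Viterbi-decode every sequence with its cohort's model."""
    out = Path(cfg.out_dir)
    profiles = {}
    rows = []
    for name, seqs in cohorts.items():
        spec = models.get(name)
        if spec is None:
            continue
        profs = []
        for s in seqs:
            path = viterbi_decode(spec, s)
            profs.append((s, zn.extract_zones(path)))
            rows.append({
                "shoot_id": s.shoot_id,
                "cohort": name,
                "states": " ".join(spec.state_names[j] for j in path.states),
            })
        profiles[name] = profs
    pd.DataFrame(rows).to_csv(out / "decoded.tsv", sep="\t", index=False)
    return profiles


def _group_label(seq: BranchingSequence, with_gp: bool = False) -> str:
    c = seq.category
    base = f"{c.cyclicity} {c.gd_class} GD" if c.cyclicity == ONE_GU else TWO_GUS
    return f"{base} ({c.gp_class})" if with_gp else base


def stage_analyze(cfg: RunConfig, cohorts: dict, models: dict,
                  profiles: dict) -> dict:
    out = Path(cfg.out_dir)
    outputs = {}

    # --- zone occurrence probabilities per category group ---
    occ_frames = []
    for name, profs in profiles.items():
        spec = models[name]
        grouped: dict[str, list] = {}
        for seq, prof in profs:
            grouped.setdefault(_group_label(seq), []).append(prof)
        tab = zn.occurrence_probabilities(
            grouped, range(spec.n_states), spec.state_names)
        tab.insert(0, "model", name)
        occ_frames.append(tab)
    if occ_frames:
        occ = pd.concat(occ_frames)
        occ.to_csv(out / "occurrence.tsv", sep="\t")
        outputs["occurrence"] = occ

    # --- zone-length comparisons between category groups ---
    zl_results = []
    for name, profs in profiles.items():
        spec = models[name]
        grouped: dict[str, list] = {}
        for seq, prof in profs:
            grouped.setdefault(_group_label(seq), []).append(prof)
        labels = sorted(grouped)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                for state in range(spec.n_states):
                    la = [p.zone_length(state) for p in grouped[labels[i]]]
                    lb = [p.zone_length(state) for p in grouped[labels[j]]]
                    la = [v for v in la if v is not None]
                    lb = [v for v in lb if v is not None]
                    r = zn.compare_zone_lengths(la, lb, state,
                                                (labels[i], labels[j]))
                    r.state = spec.state_names[state]
                    zl_results.append(r)
    if zl_results:
        zl = zn.zone_comparison_table(zl_results)
        zl.to_csv(out / "zone_lengths.tsv", sep="\t", index=False)
        outputs["zone_lengths"] = zl

    # --- lateral-type distributions within states ---
    lat_rows = []
    for name, profs in profiles.items():
        spec = models[name]
        grouped = {}
        for seq, prof in profs:
            grouped.setdefault(_group_label(seq), []).append(prof)
        labels = sorted(grouped)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                for state in range(spec.n_states):
                    if spec.emissions[state].forced_symbol is not None:
                        continue  # forced zones have a single lateral type
                    ca = zn.lateral_type_distribution(grouped[labels[i]], state)
                    cb = zn.lateral_type_distribution(grouped[labels[j]], state)
                    tab = np.vstack([ca, cb])
                    tab = tab[:, tab.sum(axis=0) > 0]
                    if tab.shape[1] < 2 or np.any(tab.sum(axis=1) == 0):
                        continue
                    fr = zn.compare_lateral_distributions(tab)
                    lat_rows.append({
                        "model": name, "state": spec.state_names[state],
                        "group_a": labels[i], "group_b": labels[j],
                        "pvalue": fr.pvalue, "method": fr.method,
                        "code": zn.significance_code(fr.pvalue),
                    })
    if lat_rows:
        lat = pd.DataFrame(lat_rows)
        lat.to_csv(out / "lateral_types.tsv", sep="\t", index=False)
        outputs["lateral_types"] = lat

    # --- diffuse-floral zone length vs total length ---
    corr_rows = []
    for name, profs in profiles.items():
        spec = models[name]
        floral = 1  # S1 / L1 are the diffuse floral zones of both models
        res = zn.correlate_zone_vs_total([p for _, p in profs], floral)
        corr_rows.append({
            "model": name, "state": spec.state_names[floral], "n": res.n,
            "r": res.r, "r_squared": res.r_squared, "note": res.note,
        })
    corr = pd.DataFrame(corr_rows)
    corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
    outputs["correlations"] = corr

    # --- node numbers and lateral counts per category ---
    all_seqs = [s for seqs in cohorts.values() for s in seqs]
    groups_nodes: dict[str, list] = {}
    for s in all_seqs:
        groups_nodes.setdefault(_group_label(s), []).append(len(s))
    groups_nodes = {g: v for g, v in groups_nodes.items() if len(v) >= 3}
    if len(groups_nodes) >= 2:
        node_res = cmp.compare_node_numbers(
            {g: np.asarray(v) for g, v in groups_nodes.items()})
        nodes = node_res.summary()
        nodes["family"] = node_res.family
        nodes.to_csv(out / "node_numbers.tsv", sep="\t", index=False)
        outputs["node_numbers"] = nodes

    lat_counts = []
    for s in all_seqs:
        row = {"group": _group_label(s)}
        for v, nm in enumerate(["latent", "short_veg", "long_veg",
                                "bourse_short", "bourse_long"]):
            row[nm] = int(np.sum(s.symbols == v))
        lat_counts.append(row)
    lc = pd.DataFrame(lat_counts)
    kw_rows = []
    for nm in ["latent", "short_veg", "long_veg", "bourse_short", "bourse_long"]:
        grouped = {g: sub[nm].to_numpy() for g, sub in lc.groupby("group")
                   if len(sub) >= 3}
        if len(grouped) < 2:
            continue
        res = cmp.compare_lateral_counts(grouped)
        kw_rows.append({"lateral_type": nm, "test": res.test,
                        "statistic": res.statistic, "pvalue": res.pvalue,
                        "code": res.code})
    if kw_rows:
        kw = pd.DataFrame(kw_rows)
        kw.to_csv(out / "lateral_counts.tsv", sep="\t", index=False)
        outputs["lateral_counts"] = kw

    # proportions: lateral types x groups contingency
    contingency = lc.groupby("group").sum()
    if contingency.shape[0] >= 2:
        pr = cmp.compare_lateral_proportions(contingency.to_numpy())
        pd.DataFrame([{
            "test": pr.test, "statistic": pr.statistic,
            "pvalue": pr.pvalue, "code": pr.code,
            "small_sample": pr.flagged_small,
        }]).to_csv(out / "lateral_proportions.tsv", sep="\t", index=False)
        outputs["lateral_proportions"] = pr
    return outputs


def _write_report(cfg: RunConfig, out: Path, cohorts: dict, models: dict,
                  outputs: dict) -> None:
    lines = ["shootzones analysis report", "=" * 26, ""]
    for name, seqs in cohorts.items():
        fitted = "fitted" if name in models else "skipped (too few sequences)"
        lines.append(f"cohort {name}: {len(seqs)} sequences, model {fitted}")
    lines.append("")
    if "occurrence" in outputs:
        lines += ["Zone occurrence probabilities:",
                  outputs["occurrence"].round(3).to_string(), ""]
    if "node_numbers" in outputs:
        lines += ["Node numbers per category (count GLM, compact letters):",
                  outputs["node_numbers"].round(2).to_string(index=False), ""]
    if "correlations" in outputs:
        lines += ["Diffuse floral zone vs total length:",
                  outputs["correlations"].round(3).to_string(index=False), ""]
    (out / "report.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the analysis outputs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    categories = None
    if cfg.growth_csv is not None:
        categories = stage_categorize(cfg)
    if cfg.sequences_tsv is None:
        logger.warning("no sequences TSV: stopping after categorisation")
        return {"categories": categories}
    seqs = read_sequences(cfg.sequences_tsv)
    seqs = _attach_categories(seqs, categories)
    if not seqs:
        raise DataError("no sequences with a category; cannot continue")
    cohorts = split_cohorts(seqs)
    models = stage_fit(cfg, cohorts)
    profiles = stage_decode(cfg, cohorts, models)
    outputs = stage_analyze(cfg, cohorts, models, profiles)
    outputs["categories"] = categories
    _write_report(cfg, out, cohorts, models, outputs)
    return outputs
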