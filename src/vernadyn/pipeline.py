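"""End-to-end orchestration of the analysis stages over tidy CSV tables.

Stages run in order: normalize -> breakpoint -> fit-decay -> compare ->
variability -> postvern -> fitness.  A stage whose input table is absent
is skipped with a logged reason; nothing is dropped silently.  Every run
writes a provenance manifest (config hash, seeds, per-stage row counts,
output file hashes) so identical configs yield identical, verifiable
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decay, fitness, groupstats, induction, postvern, qpcr

__all__ = ["RunConfig", "run_pipeline", "SchemaError"]


class SchemaError(ValueError):
    """A CSV does not match the expected column schema."""


_SCHEMAS = {
    "expression": ["genotype", "day", "gene", "value_au"],
    "qpcr": ["sample_id", "amplicon"],
    "bolting": ["genotype", "transfer_day", "days_to_bolting"],
    "fitness": ["genotype", "bolted_before_winter", "survived", "siliques"],
}


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML-loadable)."""

    out_dir: str = "run"
    expression_csv: str | None = None
    qpcr_csv: str | None = None
    bolting_csv: str | None = None
    fitness_csv: str | None = None
    target_gene: str = "FLC"
    induction_gene: str = "VIN3"
    reference_genes: tuple = ("UBC", "PP2A")
    control_genotype: str = "ColFRI"
    control_sample: str | None = None
    breakpoint: str | float = "auto"  # "auto" or a fixed day
    decay_mode: str = "two_phase"     # or "combined"
    decay_scale: str = "linear"
    exclusion_after_day: float | None = None
    alpha: float = 0.05
    fdr_q: float = 0.05
    seed: int = 0
    dunnett_mc_draws: int = 200_000
    efficiency: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        for name in ("expression_csv", "qpcr_csv", "bolting_csv", "fitness_csv"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} points to missing file: {p}")
        return cfg


def _read_csv(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for {kind} table")
    for col in _SCHEMAS[kind]:
        n_bad = int(df[col].isna().sum()) if kind != "bolting" or col != "days_to_bolting" else 0
        if n_bad == len(df) and len(df):
            raise SchemaError(f"{path}: column {col!r} is entirely missing values")
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all applicable stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    outputs: list[Path] = []

    def stage(name, **info):
        log.append({"stage": name, **info})

    # -- normalize ----------------------------------------------------------
    expr = None
    if config.qpcr_csv is not None:
        raw = _read_csv(config.qpcr_csv, "qpcr")
        kept, excl = qpcr.quality_filter(
            raw, reference_amplicons=config.reference_genes,
            efficiency=config.efficiency)
        expr = qpcr.normalize_table(
            kept, target_genes=(config.target_gene, config.induction_gene),
            reference_genes=config.reference_genes,
            efficiency=config.efficiency,
            control_sample=config.control_sample)
        _write_csv(expr, out / "normalized.csv")
        _write_csv(excl, out / "exclusions.csv")
        outputs += [out / "normalized.csv", out / "exclusions.csv"]
        stage("normalize", rows_in=len(raw), rows_out=len(expr),
              excluded=len(excl))
    elif config.expression_csv is not None:
        expr = _read_csv(config.expression_csv, "expression")
        stage("normalize", skipped="expression table supplied pre-normalized")
    else:
        stage("normalize", skipped="no qPCR or expression input")

    # -- breakpoint ---------------------------------------------------------
    bp_day = None
    bp_for_fit = None  # estimate object when detected (post-boundary), day else
    if expr is not None:
        if config.breakpoint == "auto":
            est = induction.detect_induction_from_table(
                expr, gene=config.induction_gene,
                reference_genotype=config.control_genotype)
            bp_day = est.day
            bp_for_fit = est
            (out / "breakpoint.json").write_text(json.dumps({
                "day": est.day, "baseline": est.baseline,
                "threshold": est.threshold, "method": est.method,
                "supported": est.supported, "detected": est.detected}, indent=2))
            outputs.append(out / "breakpoint.json")
            stage("breakpoint", detected=est.detected, day=est.day)
        else:
            bp_day = float(config.breakpoint)
            bp_for_fit = bp_day
            stage("breakpoint", fixed_day=bp_day)
    else:
        stage("breakpoint", skipped="no expression table")

    # -- fit-decay ----------------------------------------------------------
    features = None
    if expr is not None and (bp_day is not None or config.decay_mode == "combined"):
        features = decay.extract_features(
            expr, breakpoint=bp_for_fit, mode=config.decay_mode,
            scale=config.decay_scale,
            exclusion_after_day=config.exclusion_after_day,
            gene=config.target_gene)
        _write_csv(features, out / "features.csv")
        outputs.append(out / "features.csv")
        stage("fit-decay", genotypes=len(features))
    else:
        stage("fit-decay", skipped="no expression table or breakpoint")

    # -- compare (Dunnett on starting levels; mixed-model slopes) ----------
    if expr is not None and features is not None:
        flc = expr[expr["gene"] == config.target_gene]
        first_day = flc["day"].min()
        at_first = flc[flc["day"] == first_day]
        counts = at_first.groupby("genotype")["value_au"].count()
        usable = counts[counts >= 2].index
        if config.control_genotype in set(usable) and len(usable) >= 2:
            dunnett = groupstats.dunnett_vs_control(
                at_first[at_first["genotype"].isin(usable)]
                [["genotype", "value_au"]],
                control=config.control_genotype, alpha=config.alpha,
                mc_draws=config.dunnett_mc_draws, seed=config.seed)
            _write_csv(dunnett, out / "dunnett_starting_levels.csv")
            outputs.append(out / "dunnett_starting_levels.csv")
            stage("compare-starting", groups=len(usable))
        else:
            stage("compare-starting",
                  skipped="control absent or <2 usable groups")
        if "block" in flc.columns and flc["genotype"].nunique() >= 2:
            slopes = groupstats.mixed_slope_contrasts(
                flc, reference=config.control_genotype)
            _write_csv(slopes, out / "slope_contrasts.csv")
            outputs.append(out / "slope_contrasts.csv")
            stage("compare-slopes", genotypes=len(slopes),
                  warnings=slopes.attrs.get("warnings", []))
        else:
            stage("compare-slopes", skipped="no block column or <2 genotypes")
    else:
        stage("compare", skipped="no features")

    # -- variability --------------------------------------------------------
    if features is not None:
        cvs, tests = groupstats.variability_report(features, q=config.fdr_q)
        _write_csv(cvs, out / "variability_cvs.csv")
        _write_csv(tests, out / "variability_tests.csv")
        outputs += [out / "variability_cvs.csv", out / "variability_tests.csv"]
        stage("variability", cv_rows=len(cvs), tests=len(tests))
    else:
        stage("variability", skipped="no features")

    # -- postvern -----------------------------------------------------------
    if config.bolting_csv is not None:
        bolting = _read_csv(config.bolting_csv, "bolting")
        table = postvern.postvern_table(bolting, expression_at_transfer=expr)
        _write_csv(table, out / "postvern.csv")
        outputs.append(out / "postvern.csv")
        stage("postvern", genotypes=len(table))
    else:
        bolting = None
        stage("postvern", skipped="no bolting table")

    # -- fitness ------------------------------------------------------------
    if config.fitness_csv is not None:
        plants = _read_csv(config.fitness_csv, "fitness")
        summaries = fitness.summarize_genotypes(plants)
        _write_csv(summaries, out / "fitness_summaries.csv")
        outputs.append(out / "fitness_summaries.csv")
        results: dict = {}
        if "autumn_flc" in plants:
            results["precocious_bolting"] = fitness.precocious_bolting_model(plants)
        bolted = plants[plants["bolted_before_winter"].astype(bool)]
        nonb = plants[~plants["bolted_before_winter"].astype(bool)]
        if len(bolted) and len(nonb):
            results["survival_test"] = fitness.survival_proportion_test(
                (int(bolted["survived"].sum()), len(bolted)),
                (int(nonb["survived"].sum()), len(nonb)))
        if "postvern_m" in summaries and summaries["postvern_m"].notna().all() \
                and len(summaries) >= 4:
            results["silique_models"] = fitness.silique_models(
                summaries, plants=plants)
        (out / "fitness_models.json").write_text(
            json.dumps(results, indent=2, default=float))
        outputs.append(out / "fitness_models.json")
        stage("fitness", plants=len(plants), models=sorted(results))
    else:
        stage("fitness", skipped="no fitness table")

    # -- manifest -----------------------------------------------------------
    cfg_dict = asdict(config)
    cfg_dict["reference_genes"] = list(config.reference_genes)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "stages": log,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
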