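"""End-to-end pipeline: simulate -> QC -> trial statistics -> prediction -> report.

Every stage reads only the plain CSV/TSV files written by the stage before it
and writes its own outputs into the run directory, so any stage can be rerun
from files.  A manifest (JSON) records the configuration, the seeds and a
SHA-256 digest of every output; a rerun with the same configuration is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import phsgp
from phsgp.evaluation import (
    ScenarioSpec,
    compare_models,
    cross_season_predict,
    cross_validate,
    haplotype_analysis,
    make_folds,
    season_correlations,
)
from phsgp.gblup import VARIANTS, ModelSpec
from phsgp.genotypes import impute_missing, pca, qc_filter, recode_minor_allele, vanraden_grm
from phsgp.io import read_dosage_table, read_grm, write_dosage_table, write_grm
from phsgp.synthetic import (
    PopulationSpec,
    TrialDesignSpec,
    make_qtl_architecture,
    simulate_phenotypes,
    simulate_population,
)
from phsgp.trial import (
    TRAIT_SCALES,
    PhenotypeTable,
    adjusted_means,
    heritability_table,
    repeatability_table,
)

#: Season label -> cohorts phenotyped in that season.
SEASON_COHORTS = {"S15": ("CS", "VS15"), "S16": ("CS", "VS16")}

STAGES = ("simulate", "qc", "trial-stats", "predict-cv", "predict-season", "haplotypes")


class ConfigError(ValueError):
    """Invalid run configuration (detected before any computation)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full synthetic-data pipeline run."""

    seed: int = 1
    outdir: str = "phsgp_run"
    traits: list = field(default_factory=lambda: ["FNS"])
    variants: list = field(default_factory=lambda: ["model1", "model2_qtl17", "model2_phs"])
    population: dict = field(default_factory=dict)
    architecture: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    cv: dict = field(default_factory=lambda: {"k": 5, "reps": 10})
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [t for t in self.traits if t not in TRAIT_SCALES]
        if unknown:
            raise ConfigError(f"unknown trait names: {unknown}")
        bad = [v for v in self.variants if v not in VARIANTS]
        if bad:
            raise ConfigError(f"unknown model variants: {bad}")
        if self.population.get("seed", 0) is None or self.seed is None:
            raise ConfigError("seeds must be explicit")
        if not self.traits:
            raise ConfigError("at least one trait is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _child_seed(seed: int, *tags) -> int:
    h = hashlib.sha256(("/".join(map(str, (seed,) + tags))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


# --------------------------------------------------------------------------
# stage implementations (each reads/writes only files in the run directory)
# --------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, out: Path) -> list:
    pop = PopulationSpec(**{"seed": _child_seed(cfg.seed, "pop"), **cfg.population})
    geno = simulate_population(pop)
    arch = make_qtl_architecture(geno, seed=_child_seed(cfg.seed, "arch"), **cfg.architecture)
    write_dosage_table(geno, out / "genotypes_raw.tsv")
    eff = arch.truth_frame()
    eff["qtl_group"] = [arch.qtl_groups.get(m, "") for m in eff["marker"]]
    eff.to_csv(out / "true_effects.csv", index=False)

    design = TrialDesignSpec(**cfg.design)
    labels = pd.Series(geno.set_label, index=geno.line_ids)
    frames, truths = [], []
    for season, cohorts in SEASON_COHORTS.items():
        season_lines = labels.index[labels.isin(cohorts)].to_numpy()
        for trait in cfg.traits:
            tab, g_true = simulate_phenotypes(
                geno, arch, design,
                seed=_child_seed(cfg.seed, "pheno", season, trait),
                trait=trait, season=season, lines=season_lines,
            )
            frames.append(tab.records)
            truths.append(pd.DataFrame(
                {"season": season, "trait": trait, "line": g_true.index, "true_g": g_true.values}
            ))
    PhenotypeTable(records=pd.concat(frames, ignore_index=True)).to_csv(out / "phenotypes.csv")
    pd.concat(truths, ignore_index=True).to_csv(out / "true_breeding_values.csv", index=False)
    return ["genotypes_raw.tsv", "true_effects.csv", "phenotypes.csv",
            "true_breeding_values.csv"]


def stage_qc(cfg: RunConfig, out: Path) -> list:
    geno = recode_minor_allele(read_dosage_table(out / "genotypes_raw.tsv"))
    geno, report = qc_filter(geno, **cfg.qc)
    geno = impute_missing(geno, seed=_child_seed(cfg.seed, "impute"))
    report.to_frame().to_csv(out / "qc_report.csv", index=False)
    write_dosage_table(geno, out / "genotypes_qc.tsv")
    A = vanraden_grm(geno)
    write_grm(A, out / "relationship_matrix.csv")
    pcs = pca(geno, k=2)
    pd.DataFrame(
        {"line": pcs.line_ids, "PC1": pcs.scores[:, 0], "PC2": pcs.scores[:, 1]}
    ).to_csv(out / "pca_scores.csv", index=False)
    return ["qc_report.csv", "genotypes_qc.tsv", "relationship_matrix.csv", "pca_scores.csv"]


def stage_trial_stats(cfg: RunConfig, out: Path) -> list:
    pheno = PhenotypeTable.from_csv(out / "phenotypes.csv")
    repeatability_table(pheno).to_csv(out / "repeatability.csv", index=False)
    heritability_table(pheno).to_csv(out / "heritability.csv", index=False)
    rows = []
    for season in sorted(pheno.records["season"].unique()):
        for trait in cfg.traits:
            bl = adjusted_means(pheno, trait, season)
            rows.append(pd.DataFrame(
                {"season": season, "trait": trait, "line": bl.index, "blue": bl.values}
            ))
    pd.concat(rows, ignore_index=True).to_csv(out / "adjusted_means.csv", index=False)
    return ["repeatability.csv", "heritability.csv", "adjusted_means.csv"]


def _load_prediction_inputs(out: Path):
    geno = read_dosage_table(out / "genotypes_qc.tsv")
    A = read_grm(out / "relationship_matrix.csv")
    blues = pd.read_csv(out / "adjusted_means.csv")
    genotyped = set(geno.line_ids)
    means = {}
    for (season, trait), grp in blues.groupby(["season", "trait"]):
        s = pd.Series(grp["blue"].to_numpy(), index=grp["line"].to_numpy())
        means[(season, trait)] = s.loc[[l for l in s.index if l in genotyped]]
    eff = pd.read_csv(out / "true_effects.csv")
    return geno, A, means, eff


def model_spec_from_effects(variant: str, eff: pd.DataFrame, geno) -> ModelSpec:
    """Rebuild a model variant's covariate list from the written truth table."""
    have = set(geno.marker_ids)
    if variant == "model1":
        return ModelSpec("model1")
    if variant == "model2_qtl17":
        ids = eff.loc[eff["is_panel"], "marker"]
    elif variant == "model2_phs":
        ids = eff.loc[eff["qtl_group"] == "Phs-A1", "marker"]
    elif variant == "model2_rht":
        ids = eff.loc[eff["is_fn"], "marker"]
    else:
        raise ConfigError(f"unknown variant {variant}")
    kept = [m for m in ids if m in have]
    if not kept:
        raise ConfigError(f"no covariate markers of {variant} survived QC")
    return ModelSpec(variant, kept)


def stage_predict_cv(cfg: RunConfig, out: Path) -> list:
    geno, A, means, eff = _load_prediction_inputs(out)
    programs_of = pd.Series(geno.program, index=geno.line_ids)
    cv_rows, cmp_rows = [], []
    for season in SEASON_COHORTS:
        key = (season, cfg.traits[0])
        if key not in means:
            raise StageError(f"predict-cv: no adjusted means for {key}")
        season_lines = means[key].index.to_numpy()
        plan = make_folds(
            season_lines, programs_of.loc[season_lines].to_numpy(),
            k=cfg.cv.get("k", 5), reps=cfg.cv.get("reps", 10),
            seed=_child_seed(cfg.seed, "folds", season),
        )
        for trait in cfg.traits:
            results = {}
            for variant in cfg.variants:
                spec = model_spec_from_effects(variant, eff, geno)
                res = cross_validate(means[(season, trait)], geno, A, spec, plan, trait=trait)
                results[variant] = res
                df = res.runs.copy()
                df.insert(0, "variant", variant)
                df.insert(0, "trait", trait)
                df.insert(0, "season", season)
                cv_rows.append(df)
            for variant, res in results.items():
                if variant == "model1" or "model1" not in results:
                    continue
                c = compare_models(results["model1"], res)
                cmp_rows.append({"season": season, "trait": trait, "variant": variant, **c})
    pd.concat(cv_rows, ignore_index=True).to_csv(out / "cv_runs.csv", index=False)
    pd.DataFrame(cmp_rows).to_csv(out / "model_comparison.csv", index=False)
    return ["cv_runs.csv", "model_comparison.csv"]


def stage_predict_season(cfg: RunConfig, out: Path) -> list:
    geno, A, means, eff = _load_prediction_inputs(out)
    variant = "model2_qtl17" if "model2_qtl17" in cfg.variants else cfg.variants[0]
    rows = []
    for trait in cfg.traits:
        mbs = {s: means[(s, trait)] for s in SEASON_COHORTS}
        mspec = model_spec_from_effects(variant, eff, geno)
        for es, ts in (("S15", "S16"), ("S16", "S15")):
            for ts_subset in ("cs", "vs"):
                spec = ScenarioSpec(es, ts, "all", ts_subset, trait, variant)
                rows.append({**cross_season_predict(spec, mbs, geno, A, mspec),
                             "kind": "prediction"})
        sc = season_correlations(mbs, geno, A, mspec, ("S15", "S16"))
        for kind, r in (("obv_obv", sc["r_obv"]), ("gebv_gebv", sc["r_gebv"])):
            rows.append({"trait": trait, "variant": variant, "es": "S15:cs", "ts": "S16:cs",
                         "r": r, "n_es": sc["n_cs"], "n_ts": sc["n_cs"], "kind": kind})
    pd.DataFrame(rows).to_csv(out / "season_scenarios.csv", index=False)
    return ["season_scenarios.csv"]


def stage_haplotypes(cfg: RunConfig, out: Path) -> list:
    geno, A, means, eff = _load_prediction_inputs(out)
    pair = eff.loc[eff["is_major"], "marker"].tolist()[:2]
    frames = []
    if len(pair) == 2 and all(m in set(geno.marker_ids) for m in pair):
        for (season, trait), m in means.items():
            try:
                table, tests = haplotype_analysis(geno, pair, m)
            except ValueError:
                continue
            table = table.copy()
            table.insert(0, "trait", trait)
            table.insert(0, "season", season)
            table["n_significant_pairs"] = int(tests["significant"].sum())
            frames.append(table)
    hap = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    hap.to_csv(out / "haplotype_classes.csv", index=False)
    return ["haplotype_classes.csv"]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "trial-stats": stage_trial_stats,
    "predict-cv": stage_predict_cv,
    "predict-season": stage_predict_season,
    "haplotypes": stage_haplotypes,
}


def run_stage(name: str, cfg: RunConfig, out=None) -> list:
    out = Path(cfg.outdir if out is None else out)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _STAGE_FUNCS[name](cfg, out)
    except (ConfigError, KeyError):
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order and return the written manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_files = {}
    for name in STAGES:
        stage_files[name] = run_stage(name, cfg, out)
    manifest = {
        "package_version": phsgp.__version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": {
            stage: {f: _sha256(out / f) for f in fs} for stage, fs in stage_files.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
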