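"""Configuration-driven orchestration of the full synthetic-study pipeline.

``run_pipeline`` executes simulate -> preprocess -> cellcomp -> ewas ->
gene-set ORA -> GWAS-proximity enrichment -> replication, writes every stage
output as TSV plus a JSON run manifest, and returns the in-memory bundle.
A single global seed fans out deterministically to per-stage child seeds
that are recorded in the manifest, so a manifest alone reproduces a run.
"""
from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, synthdata
from .cellcomp import refactor_components
from .ewas import effect_size_for_t, plot_tables, run_ewas
from .genesets import hypergeom_ora, map_cpgs_to_genes
from .gwasprox import (DEFAULT_DISTANCES, compare_groups, locus_enrichment,
                       success_ratios, summarize_locus_enrichment)
from .preprocess import preprocess_pipeline
from .replication import vicinity_match

log = logging.getLogger("smokewas.pipeline")

_STAGES = ("simulate", "preprocess", "cellcomp", "ewas", "ora", "gwasprox",
           "replication")


@dataclass
class SimulateConfig:
    n_samples: int = 50
    n_probes: int = 2_000
    n_cell_types: int = 3
    noise_sd: float = 0.1
    n_interaction_probes: int = 10
    interaction_target_t: float = 8.0


@dataclass
class PreprocessConfig:
    detection_p_threshold: float = 0.01
    detection_sample_fraction: float = 0.05


@dataclass
class CellcompConfig:
    d: int = 5
    t: int = 500
    k: int = 3


@dataclass
class EwasConfig:
    m_total: Optional[int] = None
    center: bool = False
    fdr_threshold: float = 0.05
    suggestive_p: float = 1e-5


@dataclass
class OraConfig:
    n_sets: int = 20
    enriched_excess: float = 3.0
    query_p_threshold: float = 0.05


@dataclass
class GwasproxConfig:
    distances: tuple[int, ...] = DEFAULT_DISTANCES
    group_size: int = 300
    planted_distance: int = 10_000
    planted_fraction: float = 0.5
    relevant_group: str = "Phen1"
    control_group: str = "Phen4"
    n_top_cpgs: int = 20


@dataclass
class ReplicationConfig:
    window: int = 5_000
    q_threshold: float = 0.05
    fraction_validated: float = 0.5
    n_background: int = 500


@dataclass
class PipelineConfig:
    seed: int = 0
    run_ora: bool = True
    run_gwasprox: bool = True
    run_replication: bool = True
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cellcomp: CellcompConfig = field(default_factory=CellcompConfig)
    ewas: EwasConfig = field(default_factory=EwasConfig)
    ora: OraConfig = field(default_factory=OraConfig)
    gwasprox: GwasproxConfig = field(default_factory=GwasproxConfig)
    replication: ReplicationConfig = field(default_factory=ReplicationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _dataclass_from_dict(cls, data, path="config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        sim = self.simulate
        if sim.n_samples < 10:
            raise ValueError("simulate.n_samples must be at least 10")
        if sim.n_interaction_probes > sim.n_probes:
            raise ValueError("more planted probes than probes")
        if not 0 < self.preprocess.detection_p_threshold < 1:
            raise ValueError("detection_p_threshold must lie in (0, 1)")
        if not 1 <= self.cellcomp.k <= self.cellcomp.t:
            raise ValueError("need 1 <= cellcomp.k <= cellcomp.t")
        if self.replication.window < 0:
            raise ValueError("replication.window must be non-negative")


def _dataclass_from_dict(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"{path} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys under {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        default = (f.default_factory() if f.default_factory is not dataclasses.MISSING
                   else f.default)
        if dataclasses.is_dataclass(default):
            kwargs[name] = _dataclass_from_dict(type(default), value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _child_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES), dtype=np.uint32)
    return {stage: int(s % (2 ** 31)) for stage, s in zip(_STAGES, state)}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every enabled stage on synthetic data and write all outputs.

    Returns a bundle dict holding the stage tables and the manifest.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed)
    bundle: dict = {"manifest": {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": _jsonable(config.to_dict()),
        "row_counts": {},
    }}
    counts = bundle["manifest"]["row_counts"]
    current_stage = "simulate"

    def _stage(name):
        nonlocal current_stage
        current_stage = name
        log.info("stage %s starting", name)
        return time.perf_counter()

    try:
        # --- simulate -------------------------------------------------------
        t0 = _stage("simulate")
        sim = config.simulate
        cohort = synthdata.generate_cohort(sim.n_samples, seed=seeds["simulate"])
        b3 = effect_size_for_t(cohort, sim.interaction_target_t, sim.noise_sd)
        effects = {"interaction": [(j, b3) for j in range(sim.n_interaction_probes)]}
        methylome = synthdata.generate_methylome(
            cohort, sim.n_probes, sim.n_cell_types,
            effects=effects, noise_sd=sim.noise_sd, seed=seeds["simulate"] + 1)
        io.write_sample_table(cohort, outdir / "samples.tsv")
        io.write_intensities(methylome.intensities, outdir / "intensities.tsv")
        io.write_annotation(methylome.annotation, outdir / "annotation.tsv")
        methylome.truth.save(outdir / "truth.json")
        bundle.update(cohort=cohort, methylome=methylome)
        counts["simulate"] = {"samples": len(cohort), "probes": sim.n_probes}
        log.info("stage simulate done in %.2fs", time.perf_counter() - t0)

        # --- preprocess -----------------------------------------------------
        t0 = _stage("preprocess")
        beta, mvals, dropped = preprocess_pipeline(
            methylome.intensities, methylome.annotation,
            config.preprocess.detection_p_threshold,
            config.preprocess.detection_sample_fraction)
        io.write_matrix(beta, outdir / "beta.tsv")
        io.write_matrix(mvals, outdir / "mvalues.tsv")
        io.write_tsv(dropped, outdir / "dropped_probes.tsv")
        bundle.update(beta=beta, mvalues=mvals, dropped=dropped)
        counts["preprocess"] = {"kept": len(mvals.values), "dropped": len(dropped)}
        log.info("stage preprocess done in %.2fs", time.perf_counter() - t0)

        # --- cellcomp -------------------------------------------------------
        t0 = _stage("cellcomp")
        cc = config.cellcomp
        comps = refactor_components(mvals, d=cc.d,
                                    t=min(cc.t, len(mvals.values) - 1), k=cc.k)
        comp_out = comps.components.copy()
        comp_out.insert(0, "sample_id", comp_out.index)
        io.write_tsv(comp_out.reset_index(drop=True), outdir / "components.tsv")
        io.write_gene_list(comps.selected_probes, outdir / "selected_probes.txt")
        bundle["components"] = comps
        counts["cellcomp"] = {"components": cc.k, "selected_probes": len(comps.selected_probes)}
        log.info("stage cellcomp done in %.2fs", time.perf_counter() - t0)

        # --- ewas -----------------------------------------------------------
        t0 = _stage("ewas")
        results = run_ewas(mvals, cohort, comps, annotation=methylome.annotation,
                           m_total=config.ewas.m_total, center=config.ewas.center)
        io.write_tsv(results, outdir / "ewas_results.tsv")
        for name, table in plot_tables(results).items():
            io.write_tsv(table, outdir / f"plot_{name}.tsv")
        bundle["ewas"] = results
        counts["ewas"] = {"probes_tested": len(results)}
        log.info("stage ewas done in %.2fs", time.perf_counter() - t0)

        sig = results[results["interaction_tier"] == "genome_wide"]
        top = sig if len(sig) else results.nsmallest(
            config.gwasprox.n_top_cpgs, "interaction_p")

        # --- ora ------------------------------------------------------------
        if config.run_ora:
            t0 = _stage("ora")
            nominal = results[results["interaction_p"] < config.ora.query_p_threshold]
            query = map_cpgs_to_genes(list(nominal["probe_id"]), methylome.annotation)
            universe = map_cpgs_to_genes(list(results["probe_id"]), methylome.annotation)
            gene_sets = synthdata.generate_gene_sets(
                config.ora.n_sets, universe,
                enriched_set=(query, config.ora.enriched_excess) if query else None,
                seed=seeds["ora"])
            io.write_gmt(gene_sets, outdir / "gene_sets.gmt")
            io.write_gene_list(query, outdir / "query_genes.txt")
            ora = hypergeom_ora(query, gene_sets, universe)
            io.write_tsv(ora, outdir / "ora_results.tsv")
            bundle["ora"] = ora
            counts["ora"] = {"sets": len(ora), "query_genes": len(query)}
            log.info("stage ora done in %.2fs", time.perf_counter() - t0)

        # --- gwasprox -------------------------------------------------------
        if config.run_gwasprox:
            t0 = _stage("gwasprox")
            gp = config.gwasprox
            cpg_table = top[["probe_id", "chromosome", "position", "gene"]]
            targets = list(zip(cpg_table["chromosome"], cpg_table["position"]))
            genome = {c: int(length) for c, length in
                      synthdata.DEFAULT_GENOME.items() if c != "chrY"}
            cat = synthdata.generate_gwas_catalog(
                {f"Phen{i}": gp.group_size for i in range(1, 5)},
                targets,
                clustering={gp.relevant_group: (gp.planted_distance, gp.planted_fraction),
                            "Phen2": (gp.planted_distance, gp.planted_fraction / 2)},
                genome=genome, seed=seeds["gwasprox"])
            io.write_gwas_catalog(cat.catalog, outdir / "gwas_catalog.tsv")
            ratios = success_ratios(cpg_table, cat.catalog, gp.distances)
            io.write_tsv(ratios, outdir / "success_ratios.tsv")
            comparisons = []
            for other in [g for g in ("Phen1", "Phen2") if g != gp.control_group]:
                for d in gp.distances:
                    a = ratios[(ratios["group"] == other)
                               & (ratios["max_distance"] == d)]["success_ratio"]
                    b = ratios[(ratios["group"] == gp.control_group)
                               & (ratios["max_distance"] == d)]["success_ratio"]
                    u, p = compare_groups(a, b, "greater")
                    comparisons.append((other, gp.control_group, d, u, p))
            comp_table = pd.DataFrame(
                comparisons, columns=["group", "control", "max_distance", "U", "p_value"])
            io.write_tsv(comp_table, outdir / "group_comparisons.tsv")
            loci = locus_enrichment(cpg_table, cat.catalog, gp.relevant_group,
                                    gp.control_group, gp.distances)
            io.write_tsv(loci, outdir / "locus_enrichment.tsv")
            io.write_tsv(summarize_locus_enrichment(loci), outdir / "enriched_loci.tsv")
            bundle.update(success_ratios=ratios, group_comparisons=comp_table,
                          locus_enrichment=loci)
            counts["gwasprox"] = {"snps": len(cat.catalog),
                                  "cpgs": len(cpg_table),
                                  "comparisons": len(comp_table)}
            log.info("stage gwasprox done in %.2fs", time.perf_counter() - t0)

        # --- replication ----------------------------------------------------
        if config.run_replication:
            t0 = _stage("replication")
            rep_cfg = config.replication
            disc = top[["probe_id", "chromosome", "position"]]
            validation, _ = synthdata.generate_validation_table(
                disc, rep_cfg.fraction_validated, rep_cfg.n_background,
                rep_cfg.window, seed=seeds["replication"])
            io.write_tsv(validation, outdir / "validation_sites.tsv")
            rep = vicinity_match(disc, validation, rep_cfg.window, rep_cfg.q_threshold)
            io.write_tsv(rep.summary, outdir / "replication_summary.tsv")
            io.write_tsv(rep.matches, outdir / "replication_matches.tsv")
            bundle["replication"] = rep
            counts["replication"] = {"discovery": len(rep.summary),
                                     "validated": int(rep.summary["validated"].sum())}
            log.info("stage replication done in %.2fs", time.perf_counter() - t0)
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {current_stage!r}: {err}") from err

    io.write_json(bundle["manifest"], outdir / "manifest.json")
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def summarize(bundle: dict) -> str:
    """Markdown run report: tier counts per effect, top association rows,
    enrichment comparisons and the replication fraction."""
    lines = ["# Pipeline run report", ""]
    manifest = bundle.get("manifest", {})
    lines.append(f"Seed: {manifest.get('seed')} — package {manifest.get('package_version')}")
    lines.append("")
    results = bundle.get("ewas")
    if results is not None:
        lines.append("## Association results")
        for eff in ("interaction", "ic50_main", "smoking_main"):
            tiers = results[f"{eff}_tier"].value_counts()
            gw = int(tiers.get("genome_wide", 0))
            sugg = int(tiers.get("suggestive", 0))
            lines.append(f"- {eff}: {gw} genome-wide, {sugg} suggestive, "
                         f"{len(results) - gw - sugg} not significant")
        if len(results) == 0 or int((results["interaction_tier"] != "none").sum()) == 0:
            lines.append("- zero significant loci")
        if len(results):
            top = results.nsmallest(5, "interaction_p")
            lines.append("")
            lines.append("Top interaction CpGs (probe, coef, p, FDR):")
            for _, r in top.iterrows():
                lines.append(f"  - {r['probe_id']}: coef={r['interaction_coef']:.3e}, "
                             f"p={r['interaction_p']:.3e}, FDR={r['interaction_fdr']:.3g}")
        lines.append("")
    ora = bundle.get("ora")
    if ora is not None:
        lines.append("## Over-representation analysis")
        n_sig = int((ora["p_adjust"] < 0.05).sum())
        lines.append(f"- {n_sig} of {len(ora)} sets enriched at adjusted p < 0.05; "
                     f"top set {ora.iloc[0]['set_id']} (p={ora.iloc[0]['p_value']:.3g})")
        lines.append("")
    comp = bundle.get("group_comparisons")
    if comp is not None:
        lines.append("## GWAS-proximity comparisons")
        for _, r in comp.iterrows():
            lines.append(f"- {r['group']} vs {r['control']} at D={int(r['max_distance'])}: "
                         f"U={r['U']:.0f}, one-sided p={r['p_value']:.3g}")
        lines.append("")
    rep = bundle.get("replication")
    if rep is not None:
        n = len(rep.summary)
        v = int(rep.summary["validated"].sum())
        frac = v / n if n else float("nan")
        lines.append("## Replication")
        lines.append(f"- {v}/{n} discovery CpGs validated within the vicinity window "
                     f"(fraction {frac:.2f})")
        lines.append("")
    return "\n".join(lines)
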