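"""Synthetic cohorts, methylomes, gene sets and GWAS catalogs with known truth.

The generators emulate the structure of a blood-based methylation study of
drug sensitivity: a few dozen female donors aged 40-66 with lifetime smoking
histories (0 to ~270k cigarettes) and ex-vivo half-maximal inhibitory
concentrations (IC50, roughly 0.06-9.5 uM) of an antiresorptive drug; an
EPIC-style intensity table with detection p-values; a latent cell-type
mixture contributing probe-specific shifts; and planted covariate effects on
the M-value scale:

    m_ij = baseline_j + sum_c w_ic * delta_jc
           + b1_j IC50_i + b2_j Smoking_i + b3_j IC50_i*Smoking_i + b4_j Age_i
           + eps_ij,   eps ~ N(0, noise_sd)

M-values are clipped to +/- ``m_clip`` and converted to a (methylated,
unmethylated) intensity pair at fixed total signal S so that the Illumina
beta formula beta = M/(M+U+100) inverts them exactly.  Every generator is
fully deterministic under its seed, and each returns the ground truth needed
to score recovery (cell proportions, planted effect probes, planted SNPs).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import BETA_OFFSET, IntensityTable

SMOKER_CLASSES = ("never", "past", "current")

EFFECT_KINDS = ("ic50_main", "smoking_main", "interaction", "age")

#: Desk-scale genome model: chromosome name -> length in bp.
DEFAULT_GENOME = {
    "chr1": 10_000_000,
    "chr2": 10_000_000,
    "chrX": 5_000_000,
    "chrY": 2_000_000,
}


@dataclass
class CohortConfig:
    """Distributional parameters of the donor cohort.

    Defaults emulate a cohort of 34 female blood donors: ages uniform on
    [40, 66]; smoker classes (never, past, current) with probabilities
    (12, 16, 6)/34; lifetime cigarettes for ever-smokers log-uniform on
    [100, 268800] (never-smokers are 0); IC50 lognormal with median 0.28 uM,
    clipped to [0.061, 9.49] uM.
    """

    age_range: tuple[int, int] = (40, 66)
    smoker_class_probs: tuple[float, float, float] = (12 / 34, 16 / 34, 6 / 34)
    cigarettes_range: tuple[float, float] = (100.0, 268_800.0)
    ic50_range: tuple[float, float] = (0.061, 9.49)
    ic50_log_median: float = math.log(0.28)
    ic50_log_sd: float = 1.3
    log_transform_smoking: bool = False
    log_transform_ic50: bool = False

    def validate(self) -> None:
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be ordered")
        p = np.asarray(self.smoker_class_probs, float)
        if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("smoker_class_probs must be a probability vector")
        lo, hi = self.cigarettes_range
        if lo <= 0 or hi < lo:
            raise ValueError("cigarettes_range must be positive and ordered")
        ever = p[1] + p[2]
        if ever > 0 and hi == lo and ever < 1 and p[0] > 0:
            # >1 class but zero spread in the ever-smoker distribution
            raise ValueError("degenerate cigarette distribution with multiple smoker classes")
        if self.ic50_range[0] <= 0 or self.ic50_range[1] < self.ic50_range[0]:
            raise ValueError("ic50_range must be positive and ordered")
        if self.ic50_log_sd < 0:
            raise ValueError("ic50_log_sd must be non-negative")


def generate_cohort(
    n_samples: int,
    config: Optional[CohortConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a donor table with columns
    (sample_id, age, cigarettes_total, ic50, smoker_class)."""
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    classes = rng.choice(len(SMOKER_CLASSES), size=n_samples, p=cfg.smoker_class_probs)
    ages = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=n_samples)
    lo, hi = cfg.cigarettes_range
    cig = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_samples)).round()
    cig[classes == 0] = 0.0
    ic50 = rng.lognormal(cfg.ic50_log_median, cfg.ic50_log_sd, size=n_samples)
    ic50 = np.clip(ic50, *cfg.ic50_range)

    return pd.DataFrame({
        "sample_id": [f"S{i + 1:03d}" for i in range(n_samples)],
        "age": ages.astype(int),
        "cigarettes_total": cig.astype(int),
        "ic50": ic50,
        "smoker_class": [SMOKER_CLASSES[c] for c in classes],
    })


@dataclass
class TruthRecord:
    """Ground truth of one synthetic methylome run."""

    cell_proportions: pd.DataFrame          # samples x cell types, rows sum to 1
    effect_probes: dict[str, list[tuple[str, float]]]
    noise_sd: float
    seed: int

    def effect_probe_ids(self, kind: str) -> list[str]:
        return [pid for pid, _ in self.effect_probes.get(kind, [])]

    def to_json_dict(self) -> dict:
        return {
            "cell_proportions": {
                "sample_id": list(self.cell_proportions.index),
                "cell_types": list(self.cell_proportions.columns),
                "values": self.cell_proportions.to_numpy().tolist(),
            },
            "effect_probes": {k: [[p, float(s)] for p, s in v]
                              for k, v in self.effect_probes.items()},
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)


@dataclass
class MethylomeConfig:
    """Shape parameters of the synthetic methylome."""

    total_intensity: float = 10_000.0
    dirichlet_alpha: Optional[Sequence[float]] = None
    cell_informative_fraction: float = 0.2
    cell_effect_sd: float = 1.5
    baseline_levels: tuple[float, ...] = (-3.0, 0.0, 3.0)
    baseline_weights: tuple[float, ...] = (0.4, 0.2, 0.4)
    baseline_sd: float = 1.0
    m_clip: float = 6.0
    good_detection_p_max: float = 0.005
    failing_probe_fraction: float = 0.002
    failing_sample_prob: float = 0.3
    genome: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    chry_fraction: float = 0.01
    snp_overlap_fraction: float = 0.05
    gene_pool_size: Optional[int] = None
    multi_gene_fraction: float = 0.1
    no_gene_fraction: float = 0.2
    allow_shared_effect_probes: bool = False

    def alpha(self, n_cell_types: int) -> np.ndarray:
        if self.dirichlet_alpha is not None:
            a = np.asarray(self.dirichlet_alpha, float)
            if len(a) != n_cell_types:
                raise ValueError("dirichlet_alpha length must equal n_cell_types")
            return a
        # unequal mean proportions, blood-like: a geometric decay
        return 6.0 * 0.55 ** np.arange(n_cell_types) + 0.5


@dataclass
class SynthMethylome:
    """Bundle returned by :func:`generate_methylome`."""

    intensities: IntensityTable
    annotation: pd.DataFrame
    truth: TruthRecord
    mvalues: pd.DataFrame                   # probes x samples, the generative M-scale


def _normalize_effects(
    effects: Optional[Mapping[str, Sequence[tuple]]],
    probe_ids: Sequence[str],
    allow_shared: bool,
) -> dict[str, list[tuple[str, float]]]:
    index = {pid: i for i, pid in enumerate(probe_ids)}
    out: dict[str, list[tuple[str, float]]] = {}
    seen: dict[str, str] = {}
    for kind, pairs in (effects or {}).items():
        if kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {kind!r}; expected one of {EFFECT_KINDS}")
        norm = []
        for probe, size in pairs:
            pid = probe_ids[probe] if isinstance(probe, (int, np.integer)) else str(probe)
            if pid not in index:
                raise ValueError(f"effect references nonexistent probe {pid!r}")
            if not allow_shared and pid in seen and seen[pid] != kind:
                raise ValueError(f"probe {pid!r} carries effects of multiple kinds")
            seen[pid] = kind
            norm.append((pid, float(size)))
        out[kind] = norm
    return out


def generate_methylome(
    samples: pd.DataFrame,
    n_probes: int,
    n_cell_types: int = 3,
    effects: Optional[Mapping[str, Sequence[tuple]]] = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    config: Optional[MethylomeConfig] = None,
) -> SynthMethylome:
    """Simulate an intensity table, probe annotation and ground truth.

    ``effects`` maps effect kinds ('ic50_main', 'smoking_main', 'interaction',
    'age') to lists of (probe id or index, effect size on the M scale per
    covariate unit).
    """
    if n_probes < 1:
        raise ValueError("n_probes must be at least 1")
    if n_cell_types < 1:
        raise ValueError("n_cell_types must be at least 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    cfg = config or MethylomeConfig()
    rng = np.random.default_rng(seed)

    probe_ids = [f"cg{j:07d}" for j in range(1, n_probes + 1)]
    sample_ids = list(samples["sample_id"])
    n = len(sample_ids)
    eff = _normalize_effects(effects, probe_ids, cfg.allow_shared_effect_probes)

    # latent cell mixture
    w = rng.dirichlet(cfg.alpha(n_cell_types), size=n)          # n x C
    delta = np.zeros((n_probes, n_cell_types))
    informative = rng.random(n_probes) < cfg.cell_informative_fraction
    delta[informative] = rng.normal(0.0, cfg.cell_effect_sd,
                                    size=(int(informative.sum()), n_cell_types))

    # baseline methylation level, bimodal-ish as in real methylomes
    levels = rng.choice(len(cfg.baseline_levels), size=n_probes,
                        p=np.asarray(cfg.baseline_weights) / sum(cfg.baseline_weights))
    baseline = np.asarray(cfg.baseline_levels)[levels] + rng.normal(0, cfg.baseline_sd, n_probes)

    # covariate effects
    ic50 = samples["ic50"].to_numpy(float)
    smoking = samples["cigarettes_total"].to_numpy(float)
    age = samples["age"].to_numpy(float)
    covs = {
        "ic50_main": ic50,
        "smoking_main": smoking,
        "interaction": ic50 * smoking,
        "age": age,
    }
    pidx = {pid: j for j, pid in enumerate(probe_ids)}
    m = baseline[:, None] + delta @ w.T
    for kind, pairs in eff.items():
        for pid, size in pairs:
            m[pidx[pid]] += size * covs[kind]
    if noise_sd > 0:
        m = m + rng.normal(0.0, noise_sd, size=m.shape)
    m = np.clip(m, -cfg.m_clip, cfg.m_clip)

    # intensity synthesis at fixed total signal S: beta = Msig/(Msig+U+100)
    s = cfg.total_intensity
    beta = np.power(2.0, m) / (1.0 + np.power(2.0, m))
    msig = beta * s
    usig = s - msig - BETA_OFFSET
    if (usig < 0).any():
        raise ValueError("m_clip too large for total_intensity: negative U signal")

    det = rng.uniform(0.0, cfg.good_detection_p_max, size=(n_probes, n))
    failing = rng.random(n_probes) < cfg.failing_probe_fraction
    fail_mask = failing[:, None] & (rng.random((n_probes, n)) < cfg.failing_sample_prob)
    det[fail_mask] = rng.uniform(0.011, 0.8, size=int(fail_mask.sum()))

    intens = IntensityTable(
        pd.DataFrame(msig, index=probe_ids, columns=sample_ids),
        pd.DataFrame(usig, index=probe_ids, columns=sample_ids),
        pd.DataFrame(det, index=probe_ids, columns=sample_ids),
    )
    annotation = _generate_annotation(probe_ids, cfg, rng)
    truth = TruthRecord(
        cell_proportions=pd.DataFrame(w, index=sample_ids,
                                      columns=[f"cell{c + 1}" for c in range(n_cell_types)]),
        effect_probes=eff,
        noise_sd=noise_sd,
        seed=seed,
    )
    mvalues = pd.DataFrame(m, index=probe_ids, columns=sample_ids)
    return SynthMethylome(intens, annotation, truth, mvalues)


def _generate_annotation(probe_ids, cfg: MethylomeConfig, rng) -> pd.DataFrame:
    n_probes = len(probe_ids)
    chroms = list(cfg.genome)
    non_y = [c for c in chroms if c.lower().lstrip("chr") not in ("y",) and c != "chrY"]
    lengths = np.array([cfg.genome[c] for c in non_y], float)
    pick = rng.choice(len(non_y), size=n_probes, p=lengths / lengths.sum())
    chosen = np.array([non_y[i] for i in pick], dtype=object)
    if "chrY" in cfg.genome and cfg.chry_fraction > 0:
        chosen[rng.random(n_probes) < cfg.chry_fraction] = "chrY"
    positions = np.array([rng.integers(1, cfg.genome[c] + 1) for c in chosen])
    snp = rng.random(n_probes) < cfg.snp_overlap_fraction

    pool = cfg.gene_pool_size or max(1, n_probes // 5)
    genes = [f"GENE{g + 1:05d}" for g in range(pool)]
    u = rng.random(n_probes)
    assigned = []
    for j in range(n_probes):
        if u[j] < cfg.no_gene_fraction:
            assigned.append("")
        elif u[j] < cfg.no_gene_fraction + cfg.multi_gene_fraction:
            g1, g2 = rng.choice(pool, size=2, replace=False)
            assigned.append(f"{genes[g1]};{genes[g2]}")
        else:
            assigned.append(genes[rng.integers(pool)])
    return pd.DataFrame({
        "probe_id": probe_ids,
        "chromosome": chosen,
        "position": positions.astype(int),
        "gene": assigned,
        "snp_overlap": snp,
    })


@dataclass
class GwasCatalogResult:
    """Synthetic SNP catalog plus the record of which SNPs were planted."""

    catalog: pd.DataFrame           # snp_id, chromosome, position, pvalue, group
    planted: pd.DataFrame           # snp_id, planted (bool), target_index


def generate_gwas_catalog(
    groups: Mapping[str, int],
    probe_targets: Sequence[tuple[str, int]],
    clustering: Optional[Mapping[str, tuple[int, float]]] = None,
    genome: Optional[Mapping[str, int]] = None,
    seed: int = 0,
    pvalue_range: tuple[float, float] = (1e-12, 5e-6),
) -> GwasCatalogResult:
    """Simulate a phenotype-grouped SNP catalog.

    ``clustering`` maps a group name to (distance in bp, fraction): that
    fraction of the group's SNPs is placed strictly within the distance of a
    randomly chosen target CpG; the remainder (and all other groups) are
    placed uniformly on the genome model.
    """
    genome = dict(genome or {k: v for k, v in DEFAULT_GENOME.items() if k != "chrY"})
    clustering = dict(clustering or {})
    for g, size in groups.items():
        if size < 1:
            raise ValueError(f"group {g!r} must have at least 1 SNP")
    for g, (dist, frac) in clustering.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"clustering fraction for {g!r} must lie in [0, 1]")
        if frac > 0 and len(probe_targets) == 0:
            raise ValueError("nonzero clustering fraction requires a non-empty target list")
        if dist < 2:
            raise ValueError("clustering distance must be at least 2 bp (strict window)")
    rng = np.random.default_rng(seed)

    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], float)
    rows, planted_rows = [], []
    counter = 0
    for g in groups:
        dist, frac = clustering.get(g, (0, 0.0))
        for _ in range(groups[g]):
            counter += 1
            snp_id = f"rs{counter:07d}"
            if rng.random() < frac:
                ti = int(rng.integers(len(probe_targets)))
                chrom, pos = probe_targets[ti]
                offset = int(rng.integers(1, dist)) * (1 if rng.random() < 0.5 else -1)
                newpos = int(np.clip(pos + offset, 1, genome.get(chrom, pos + abs(offset))))
                rows.append((snp_id, chrom, newpos, g))
                planted_rows.append((snp_id, True, ti))
            else:
                ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
                rows.append((snp_id, chroms[ci], int(rng.integers(1, genome[chroms[ci]] + 1)), g))
                planted_rows.append((snp_id, False, -1))
    catalog = pd.DataFrame(rows, columns=["snp_id", "chromosome", "position", "group"])
    lo, hi = pvalue_range
    catalog["pvalue"] = np.exp(rng.uniform(math.log(lo), math.log(hi), size=len(catalog)))
    catalog = catalog[["snp_id", "chromosome", "position", "pvalue", "group"]]
    planted = pd.DataFrame(planted_rows, columns=["snp_id", "planted", "target_index"])
    return GwasCatalogResult(catalog, planted)


def generate_gene_sets(
    n_sets: int,
    universe: Sequence[str],
    enriched_set: Optional[tuple[Sequence[str], float]] = None,
    set_size_range: tuple[int, int] = (10, 100),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Simulate a GMT-writable gene-set collection.

    If ``enriched_set=(genes, excess)`` is given, the first set samples the
    provided genes with ``excess``-fold weight relative to the rest of the
    universe, giving over-representation analyses a known positive.
    """
    if n_sets < 0:
        raise ValueError("n_sets must be non-negative")
    universe = list(universe)
    if n_sets > 0 and not universe:
        raise ValueError("empty universe")
    rng = np.random.default_rng(seed)
    lo, hi = set_size_range
    if n_sets > 0:
        if lo > len(universe):
            raise ValueError("requested set size exceeds universe size")
        hi = min(hi, len(universe))

    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i == 0 and enriched_set is not None:
            genes, excess = enriched_set
            if excess <= 0:
                raise ValueError("enrichment excess must be positive")
            weight = np.ones(len(universe))
            marked = set(genes)
            for j, gname in enumerate(universe):
                if gname in marked:
                    weight[j] = excess
            weight /= weight.sum()
            idx = rng.choice(len(universe), size=size, replace=False, p=weight)
            sets["GS_ENRICHED"] = [universe[j] for j in idx]
        else:
            idx = rng.choice(len(universe), size=size, replace=False)
            sets[f"GS{i + 1:04d}"] = [universe[j] for j in idx]
    return sets


def generate_validation_table(
    discovery: pd.DataFrame,
    fraction_validated: float = 0.5,
    n_background: int = 500,
    window: int = 5_000,
    genome: Optional[Mapping[str, int]] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate an external validation table (site, chromosome, position, q_value).

    A ``fraction_validated`` of the discovery CpGs get a significant site
    (q < 0.05) planted within ``window`` bp; background sites are uniform on
    the genome with q ~ U(0, 1).  Returns the table and the list of discovery
    probe ids that were planted as validated.
    """
    if not 0.0 <= fraction_validated <= 1.0:
        raise ValueError("fraction_validated must lie in [0, 1]")
    genome = dict(genome or {k: v for k, v in DEFAULT_GENOME.items() if k != "chrY"})
    rng = np.random.default_rng(seed)
    rows, planted = [], []
    counter = 0
    for _, row in discovery.iterrows():
        if rng.random() < fraction_validated:
            counter += 1
            offset = int(rng.integers(-window, window + 1))
            pos = max(1, int(row["position"]) + offset)
            rows.append((f"vs{counter:05d}", row["chromosome"], pos,
                         float(rng.uniform(1e-8, 0.049))))
            planted.append(row["probe_id"])
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], float)
    for _ in range(n_background):
        counter += 1
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        rows.append((f"vs{counter:05d}", chroms[ci],
                     int(rng.integers(1, genome[chroms[ci]] + 1)),
                     float(rng.uniform(0.0, 1.0))))
    table = pd.DataFrame(rows, columns=["site_id", "chromosome", "position", "q_value"])
    return table, planted
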