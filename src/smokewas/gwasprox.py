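"""CpG-SNP proximity enrichment against phenotype-grouped GWAS catalogs.

For a CpG and a group of GWAS-associated SNPs, the *success ratio* at a
maximal distance D is the fraction of the group's SNPs lying strictly within
D bp of the CpG on the same chromosome.  Ratios computed over an incremental
distance ladder (1 kb to 50 kb by default) are compared between a relevant
phenotype group and a negative-control group with a one-tailed Mann-Whitney
U test; per-locus enrichment is additionally quantified by a one-sided
Fisher's exact test on the 2x2 within-D / beyond-D x relevant / control
contingency table, BH-adjusted across loci at each distance.

Cross-chromosome CpG-SNP pairs count as never successful.  GWAS datasets are
pre-filtered to high-confidence, heritable traits (h2 > 0.01, h2 z-score
>= 7), and catalogs are restricted to association-significant SNPs
(p < 5e-6 retained by default).
"""
from __future__ import annotations

import warnings
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import normalize_chromosome
from .ewas import bh_fdr

#: Incremental maximal distances (bp) tested by default.
DEFAULT_DISTANCES = (1_000, 2_500, 5_000, 10_000, 25_000, 50_000)

#: Largest pooled sample size for which the Mann-Whitney p is computed by
#: exact enumeration of label assignments (tie-safe); larger samples use the
#: normal approximation with tie correction.
EXACT_MAX_TOTAL = 12


def filter_gwas_datasets(
    metadata: pd.DataFrame,
    h2_min: float = 0.01,
    h2_z_min: float = 7.0,
    confidence_label: str = "high",
) -> pd.DataFrame:
    """Keep datasets flagged high-confidence with h2 > ``h2_min`` and
    h2 z-score >= ``h2_z_min``."""
    for col in ("confidence", "h2", "h2_z"):
        if col not in metadata.columns:
            raise KeyError(f"metadata is missing required column {col!r}")
    keep = (
        (metadata["confidence"].astype(str).str.lower() == confidence_label)
        & (metadata["h2"].astype(float) > h2_min)
        & (metadata["h2_z"].astype(float) >= h2_z_min)
    )
    return metadata[keep].reset_index(drop=True)


def filter_snps(
    catalog: pd.DataFrame,
    p_cutoff: float = 5e-6,
    keep: str = "below",
) -> pd.DataFrame:
    """Restrict a catalog by association p-value.

    ``keep='below'`` (default) retains SNPs with p < cutoff, i.e. the
    GWAS-suggestive associations that a proximity-enrichment test needs;
    ``keep='above'`` inverts the rule.
    """
    if keep not in ("below", "above"):
        raise ValueError("keep must be 'below' or 'above'")
    mask = catalog["pvalue"].astype(float) < p_cutoff
    if keep == "above":
        mask = ~mask
    return catalog[mask].reset_index(drop=True)


def _group_positions(catalog: pd.DataFrame) -> dict[str, dict[str, np.ndarray]]:
    """group -> chromosome -> sorted positions."""
    out: dict[str, dict[str, np.ndarray]] = {}
    chroms = catalog["chromosome"].map(normalize_chromosome)
    for (group, chrom), sub in catalog.groupby([catalog["group"], chroms],
                                               sort=False, observed=True):
        out.setdefault(group, {})[chrom] = np.sort(sub["position"].to_numpy(np.int64))
    return out


def success_ratios(
    cpgs: pd.DataFrame,
    catalog: pd.DataFrame,
    distances: Sequence[int] = DEFAULT_DISTANCES,
) -> pd.DataFrame:
    """Per-CpG success ratios for every phenotype group and distance.

    ``cpgs`` needs columns (probe_id or cpg_id, chromosome, position).  A SNP
    is successful for a CpG iff it sits on the same chromosome strictly
    closer than the maximal distance D.  Returns one row per
    CpG x group x distance with columns cpg_id, group, max_distance,
    successes, group_total, success_ratio.  Groups with zero SNPs produce a
    missing ratio and a warning.
    """
    if any(d <= 0 for d in distances):
        raise ValueError("distances must be positive")
    cpgs = cpgs.rename(columns={"probe_id": "cpg_id"})
    groups = _group_positions(catalog)
    # observed=False keeps declared-but-empty categorical groups visible
    totals = catalog.groupby("group", observed=False).size().to_dict()
    empty = [g for g, t in totals.items() if t == 0]
    if empty:
        warnings.warn(f"groups with zero SNPs: {empty}")

    rows = []
    for _, row in cpgs.iterrows():
        chrom = normalize_chromosome(row["chromosome"])
        pos = int(row["position"])
        for group, total in totals.items():
            arr = groups.get(group, {}).get(chrom)
            for d in distances:
                if total == 0:
                    rows.append((row["cpg_id"], group, int(d), 0, 0, np.nan))
                    continue
                if arr is None:
                    succ = 0
                else:
                    # strict window (pos-d, pos+d): exclude both endpoints
                    lo = np.searchsorted(arr, pos - d, side="right")
                    hi = np.searchsorted(arr, pos + d, side="left")
                    succ = int(hi - lo)
                rows.append((row["cpg_id"], group, int(d), succ, total, succ / total))
    return pd.DataFrame(
        rows,
        columns=["cpg_id", "group", "max_distance", "successes", "group_total",
                 "success_ratio"],
    )


def compare_groups(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    alternative: str = "greater",
) -> tuple[float, float]:
    """One-tailed Mann-Whitney U test between two success-ratio samples.

    Returns (U statistic of sample a, one-sided p).  For pooled sizes up to
    12 the p-value is exact, computed by enumerating all C(na+nb, na) label
    assignments of the pooled (midrank-tied) values; larger samples use the
    normal approximation with tie correction.  ``alternative='greater'``
    tests whether a tends to exceed b; 'less' the reverse.
    """
    a = np.asarray(ratios_a, float)
    b = np.asarray(ratios_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)

    if na + nb <= EXACT_MAX_TOTAL:
        offset = na * (na + 1) / 2
        total = comb(na + nb, na)
        hits = 0
        for idx in combinations(range(na + nb), na):
            u = ranks[list(idx)].sum() - offset
            if alternative == "greater":
                hits += u >= u_a - 1e-9
            else:
                hits += u <= u_a + 1e-9
        return u_a, hits / total

    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def locus_enrichment(
    cpgs: pd.DataFrame,
    catalog: pd.DataFrame,
    relevant_group: str,
    control_group: str,
    distances: Sequence[int] = DEFAULT_DISTANCES,
) -> pd.DataFrame:
    """Per-locus enrichment of relevant-group SNPs near each CpG.

    For each CpG and distance D, counts of relevant/control SNPs within vs
    beyond D form a 2x2 table tested by a one-sided Fisher's exact test for
    an excess of relevant SNPs near the CpG; BH adjustment is across loci
    within each D.  Returns columns cpg_id, gene, max_distance,
    relevant_within, control_within, p_value, fdr.
    """
    for g in (relevant_group, control_group):
        if (catalog["group"] == g).sum() == 0:
            raise ValueError(f"group {g!r} has no SNPs")
    cpgs = cpgs.rename(columns={"probe_id": "cpg_id"})
    sub = catalog[catalog["group"].isin([relevant_group, control_group])].copy()
    sub["group"] = sub["group"].astype(str)
    counts = success_ratios(cpgs, sub, distances)
    n_rel = int((catalog["group"] == relevant_group).sum())
    n_ctl = int((catalog["group"] == control_group).sum())

    wide = counts.pivot_table(index=["cpg_id", "max_distance"], columns="group",
                              values="successes", aggfunc="first")
    gene_map = (cpgs.set_index("cpg_id")["gene"].to_dict()
                if "gene" in cpgs.columns else {})
    rows = []
    for (cpg, d), rec in wide.iterrows():
        a = int(rec[relevant_group])
        c = int(rec[control_group])
        table = [[a, n_rel - a], [c, n_ctl - c]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append((cpg, gene_map.get(cpg, ""), int(d), a, c, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["cpg_id", "gene", "max_distance",
                                      "relevant_within", "control_within", "p_value"])
    out["fdr"] = np.nan
    for d in out["max_distance"].unique():
        mask = out["max_distance"] == d
        out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "p_value"])
    return out


def summarize_locus_enrichment(
    table: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One row per enriched locus: the largest tested distance with FDR below
    threshold, with that distance's p and FDR."""
    sig = table[table["fdr"] < fdr_threshold]
    if len(sig) == 0:
        return pd.DataFrame(columns=["cpg_id", "gene", "max_distance", "p_value", "fdr"])
    idx = sig.groupby("cpg_id")["max_distance"].idxmax()
    out = sig.loc[idx, ["cpg_id", "gene", "max_distance", "p_value", "fdr"]]
    return out.sort_values("fdr", kind="mergesort").reset_index(drop=True)


def success_ratio_histogram(
    ratios: pd.DataFrame,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Histogram of log2 success ratios per group and distance.

    Zero ratios have no log2; they are excluded from the bins and reported in
    the ``n_zero`` column instead.
    """
    rows = []
    for (group, d), sub in ratios.groupby(["group", "max_distance"]):
        vals = sub["success_ratio"].dropna().to_numpy(float)
        nz = vals[vals > 0]
        n_zero = int((vals == 0).sum())
        if len(nz) == 0:
            continue
        logs = np.log2(nz)
        counts, edges = np.histogram(logs, bins=n_bins)
        for i in range(n_bins):
            rows.append((group, int(d), edges[i], edges[i + 1], int(counts[i]), n_zero))
    return pd.DataFrame(rows, columns=["group", "max_distance", "bin_left",
                                       "bin_right", "count", "n_zero"])


def per_snp_success(
    cpgs: pd.DataFrame,
    catalog: pd.DataFrame,
    distances: Sequence[int] = DEFAULT_DISTANCES,
) -> pd.DataFrame:
    """Dual per-SNP view: for every SNP and distance, how many of the query
    CpGs lie strictly within D, and that count as a fraction of all CpGs."""
    cpgs = cpgs.rename(columns={"probe_id": "cpg_id"})
    n_cpgs = len(cpgs)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in cpgs.groupby(cpgs["chromosome"].map(normalize_chromosome)):
        by_chrom[chrom] = np.sort(sub["position"].to_numpy(np.int64))
    rows = []
    for _, row in catalog.iterrows():
        arr = by_chrom.get(normalize_chromosome(row["chromosome"]))
        pos = int(row["position"])
        for d in distances:
            if arr is None:
                within = 0
            else:
                lo = np.searchsorted(arr, pos - d, side="right")
                hi = np.searchsorted(arr, pos + d, side="left")
                within = int(hi - lo)
            rows.append((row["snp_id"], row["group"], int(d), within,
                         within / n_cpgs if n_cpgs else np.nan))
    return pd.DataFrame(rows, columns=["snp_id", "group", "max_distance",
                                       "cpgs_within", "success_ratio"])
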