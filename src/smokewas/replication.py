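"""Vicinity-based replication against an external association study.

A discovery CpG is considered replicated when at least one site in the
validation table lies on the same chromosome within a window (default
+/- 5 kb, boundary inclusive) and is itself significant there at FDR
q < 0.05 (strict).  Matching runs on a sorted per-chromosome position index,
so each query costs O(log n) against arbitrarily large validation tables.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import normalize_chromosome


@dataclass
class ReplicationResult:
    """Per-CpG summary plus the long-form match table (nearest first)."""

    summary: pd.DataFrame   # cpg_id, chromosome, position, n_matches, best_q, validated
    matches: pd.DataFrame   # cpg_id, site_id, distance, q_value

    @property
    def validated_fraction(self) -> float:
        if len(self.summary) == 0:
            return float("nan")
        return float(self.summary["validated"].mean())


def vicinity_match(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    window: int = 5_000,
    q_threshold: float = 0.05,
) -> ReplicationResult:
    """Match discovery CpGs to validation sites within ``window`` bp.

    ``discovery`` needs (probe_id or cpg_id, chromosome, position);
    ``validation`` needs (site_id, chromosome, position, q_value).  All
    same-chromosome sites at |delta position| <= window are listed, nearest
    first; a CpG is validated iff any such site has q < ``q_threshold``.
    Chromosome labels in either convention ("chr1"/"1") are normalized, with
    a warning when the two tables mix conventions.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    discovery = discovery.rename(columns={"probe_id": "cpg_id"})

    def _convention(series: pd.Series) -> str:
        return "ucsc" if series.astype(str).str.lower().str.startswith("chr").any() else "bare"

    if _convention(discovery["chromosome"]) != _convention(validation["chromosome"]):
        warnings.warn("chromosome label conventions differ between tables; normalizing")

    by_chrom: dict[str, pd.DataFrame] = {}
    vchrom = validation["chromosome"].map(normalize_chromosome)
    for chrom, sub in validation.groupby(vchrom):
        by_chrom[chrom] = sub.sort_values("position", kind="mergesort").reset_index(drop=True)

    summary_rows, match_rows = [], []
    for _, row in discovery.iterrows():
        chrom = normalize_chromosome(row["chromosome"])
        pos = int(row["position"])
        sub = by_chrom.get(chrom)
        hits = []
        if sub is not None:
            arr = sub["position"].to_numpy(np.int64)
            lo = np.searchsorted(arr, pos - window, side="left")
            hi = np.searchsorted(arr, pos + window, side="right")
            for i in range(lo, hi):
                hits.append((abs(int(arr[i]) - pos), sub.at[i, "site_id"],
                             float(sub.at[i, "q_value"])))
        hits.sort(key=lambda h: (h[0], h[1]))
        validated = any(q < q_threshold for _, _, q in hits)
        best_q = min((q for _, _, q in hits), default=np.nan)
        summary_rows.append((row["cpg_id"], row["chromosome"], pos,
                             len(hits), best_q, validated))
        for dist_, site, q in hits:
            match_rows.append((row["cpg_id"], site, dist_, q))

    summary = pd.DataFrame(summary_rows, columns=["cpg_id", "chromosome", "position",
                                                  "n_matches", "best_q", "validated"])
    matches = pd.DataFrame(match_rows, columns=["cpg_id", "site_id", "distance", "q_value"])
    return ReplicationResult(summary, matches)
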