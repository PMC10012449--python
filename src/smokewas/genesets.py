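"""CpG-to-gene mapping and hypergeometric over-representation analysis (ORA).

Array annotations attach zero or more gene symbols to each probe
(";"-separated for multi-gene probes, e.g. "AFMID;TK1").  ORA asks whether a
query gene list overlaps a given gene set more than chance: with a universe
of N genes, K of them in the set, and a query of n genes overlapping the set
in k, the one-sided upper-tail p-value is P(X >= k) for X hypergeometric.
Adjustment across sets is Benjamini-Hochberg; the reported q-value column
equals the BH-adjusted value (a separate Storey-type estimator is not
computed, the two are typically near-identical for well-behaved set
collections).
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .ewas import bh_fdr


def map_cpgs_to_genes(cpgs: Sequence[str], annotation: pd.DataFrame) -> list[str]:
    """Unique genes linked to the given probes, order-stable.

    Splits ";"-separated multi-gene fields, drops empty fields, and
    deduplicates while preserving first-seen order.
    """
    ann = annotation.set_index("probe_id")["gene"]
    missing = [c for c in cpgs if c not in ann.index]
    if missing:
        raise KeyError(f"{len(missing)} probes missing from annotation, e.g. {missing[0]!r}")
    seen: dict[str, None] = {}
    for cpg in cpgs:
        fld = ann.loc[cpg]
        if not isinstance(fld, str) or not fld:
            continue
        for gene in fld.split(";"):
            gene = gene.strip()
            if gene:
                seen.setdefault(gene, None)
    return list(seen)


def hypergeom_ora(
    query: Sequence[str],
    sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    descriptions: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """One-sided hypergeometric ORA of a gene list against a set collection.

    Query and every set are intersected with the universe first; the
    effective query size n is the post-intersection count.  Returns one row
    per set, sorted by p, with columns set_id, description, bg_count,
    universe_size, query_size, overlap, p_value, p_adjust, q_value.
    """
    uni: dict[str, None] = {}
    for g in universe:
        uni.setdefault(g, None)
    if not uni:
        raise ValueError("empty universe")
    uni_set = set(uni)
    q: dict[str, None] = {}
    for g in query:
        if g in uni_set:
            q.setdefault(g, None)
    if not q:
        raise ValueError("empty query after intersection with the universe")
    n_universe, n_query = len(uni), len(q)
    qset = set(q)

    rows = []
    for set_id, genes in sets.items():
        members = set(genes) & uni_set
        overlap = len(members & qset)
        # P(X >= k) with population N, K successes, n draws
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_query))
        rows.append({
            "set_id": set_id,
            "description": (descriptions or {}).get(set_id, set_id),
            "bg_count": len(members),
            "universe_size": n_universe,
            "query_size": n_query,
            "overlap": overlap,
            "p_value": min(max(p, 5e-324), 1.0),
        })
    out = pd.DataFrame(rows)
    out["p_adjust"] = bh_fdr(out["p_value"])
    out["q_value"] = out["p_adjust"]
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
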