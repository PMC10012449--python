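"""Bundled reference tables.

The package ships one small table: the 59-CpG top table of a published
epigenome-wide interaction study of smoking-dependent osteoclast sensitivity
to zoledronic acid in 34 female blood donors (per-CpG coefficient, t-value,
p-value, genomic location, FDR, linked gene, and whether a bone-mineral-
density association lies within 5 kb).  It serves as a worked example for
top-list FDR adjustment against a full epigenome-wide test count and for the
significance-tier rules.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

#: CpGs remaining after quality control in the study the bundled top table
#: comes from; the number of tests its FDR column was adjusted against.
TOP_TABLE_M_TOTAL = 683_408


def load_example_top_table() -> pd.DataFrame:
    """The bundled 59-CpG interaction top table.

    Columns: locus, cpg_id, coefficient, t_value, p_value, chromosome,
    position, fdr, gene, bmd_association.
    """
    ref = resources.files("smokewas") / "data" / "ewas_top_table.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"chromosome": str})
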