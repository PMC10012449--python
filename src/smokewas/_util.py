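"""Small shared helpers."""
from __future__ import annotations


def normalize_chromosome(label: object) -> str:
    """Normalize a chromosome label to a bare, upper-case name.

    Accepts either UCSC-style ("chr1", "chrX") or Ensembl-style ("1", "X")
    labels and returns the bare form, so that tables from different sources
    can be joined on chromosome.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper()
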