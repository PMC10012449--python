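"""Hypergeometric over-representation analysis of CpG-linked genes.

Maps nominally significant CpGs to genes (splitting multi-gene annotations
like "AFMID;TK1"), builds a gene-set collection with one set known to
over-sample the query 3-fold, and runs the one-sided hypergeometric test.
"""
import smokewas as sw
from smokewas.synthdata import generate_gene_sets

cohort = sw.generate_cohort(50, seed=7)
my = sw.generate_methylome(cohort, 2_000, seed=8)

# take an arbitrary query of probes and map them to genes
query_genes = sw.map_cpgs_to_genes(list(my.annotation.probe_id[:60]), my.annotation)
universe = sw.map_cpgs_to_genes(list(my.annotation.probe_id), my.annotation)
print(f"query: {len(query_genes)} genes; universe: {len(universe)} genes")

sets = generate_gene_sets(20, universe, enriched_set=(query_genes, 3.0), seed=9)
ora = sw.hypergeom_ora(query_genes, sets, universe)

print()
print(ora.head(5).to_string(index=False))
# The planted GS_ENRICHED set should top the table: its members were drawn
# with 3x weight on the query genes, so its overlap k exceeds the
# hypergeometric expectation K*n/N and the upper-tail p is small.
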