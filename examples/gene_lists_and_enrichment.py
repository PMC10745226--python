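"""Gene-list algebra and binomial pathway overrepresentation.

Loads the synthetic supplementary-style workbook (disease gene list with
transcript IDs, up/down differential-expression lists), reproduces the list
arithmetic, and runs the binomial enrichment test with its three reporting
filters on a toy pathway universe.
"""

import tempfile
from pathlib import Path

from adaredit.genesets import (
    GeneSet,
    PathwayUniverse,
    enrich,
    intersect,
    load_gene_list,
    union_unique,
)
from adaredit.simulate import write_synthetic_s1_workbook

with tempfile.TemporaryDirectory() as tmp:
    wb = write_synthetic_s1_workbook(Path(tmp) / "s1_synthetic.xlsx")
    pd_genes = load_gene_list(wb, "gene_id", sheet="NCBI PD Gene List", name="PD")
    pd_tx = load_gene_list(wb, "transcript_id", sheet="NCBI PD Gene List")
    up = load_gene_list(wb, "gene_id", sheet="Lavin Up", name="up")
    down = load_gene_list(wb, "gene_id", sheet="Lavin Down", name="down")

de = union_unique(up, down)
goi = intersect(pd_genes, de)
print(f"disease list: {len(pd_genes)} genes, {len(pd_tx)} transcript IDs")
print(f"DE list: {len(up)} up + {len(down)} down = {len(de)} unique genes")
print(f"genes of interest (intersection): {len(goi)}")

# enrichment: a 200-gene pathway in a 2000-gene universe (10% base rate)
pathway = frozenset(f"p{i}" for i in range(200))
background = pathway | frozenset(f"x{i}" for i in range(1800))
uni = PathwayUniverse(pathways={"Immune System": pathway}, universe=background)
query = GeneSet("edited", frozenset([f"p{i}" for i in range(15)] + [f"x{i}" for i in range(35)]))
res = enrich(query, uni, min_genes=10, min_fraction=0.10, alpha=0.05)
row = res.iloc[0]
print(f"\npathway {row['pathway']!r}: k={row['k']} of n={row['n']} "
      f"(K={row['K']}, N={row['N']}), p={row['p_value']:.2e}, fdr={row['fdr']:.2e}, "
      f"reported={bool(row['reported'])}")
# 'reported' is True because all three filters hold: >=10 query genes in the
# pathway, >=10% of the query list, and BH FDR < 0.05.
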