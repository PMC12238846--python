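"""Design a focused CRISPRi library for a set of target genes.

Guides are NGG-adjacent 20-mers whose cut site falls in [-300, +50]
around the TSS; each is scored for specificity (100 = no off-target
site, 0 = a second perfect match) and the top 10 with score >= 70 are
kept per gene, plus 50 scrambled controls with no genomic site within
two mismatches.
"""

import lncscreen as L

config = L.SimConfig(seed=3, n_genes=25, n_chroms=1)
bundle = L.simulate_annotation(config)
targets = list(bundle.annotation.genes["gene_id"][:10])

library = L.design_library(bundle, targets, guides_per_gene=10, min_score=70,
                           n_scrambled=50, seed=3)

targeting = library.guides_of_class("targeting")
print(f"composition:        {library.composition()}")
print(f"score range:        {targeting['offtarget_score'].min():.1f} .. "
      f"{targeting['offtarget_score'].max():.1f}")
print(f"cut-site offsets:   {int(targeting['cut_offset'].min())} .. "
      f"{int(targeting['cut_offset'].max())} bp relative to TSS")
print(f"genes short of 10:  {len(library.shortfalls)}")
print(f"genes excluded:     {len(library.exclusions)}")
print("\nfirst guides:")
print(targeting[["guide_id", "protospacer", "pam", "cut_offset", "offtarget_score"]]
      .head(5).to_string(index=False))
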