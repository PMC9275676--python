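"""Prioritized genomic-context annotation and region-derived gene sets.

Annotates differential regions with one of eight prioritized contexts
(Promoter.Up > Promoter.Down > Exons > Introns > TES > 5' Distal >
3' Distal > Intergenic), assigns them to genes via promoter (TSS +/- 2 kb)
or putative-enhancer (+/- 50 kb) association, and emits the genes of
up-called regions as a GMT-ready set.
"""

import pandas as pd

from chromshift import annotate, simulate

genome = simulate.simulate_genome(
    n_chroms=1, chrom_length=2_000_000, n_genes=12, gene_length_range=(20_000, 40_000), seed=3
)
g = genome.genes[0]
regions = pd.DataFrame(
    {
        "chrom": "chr1",
        "start": [g.tss - 1_500, g.tss + 30_000, 1_900_000],
        "end": [g.tss - 500, g.tss + 30_500, 1_900_400],
    }
)

context = annotate.assign_context(regions, genome)
assignments = annotate.assign_genes(regions, genome)
print("context labels:")
print(context.to_string())
print("\ngene assignments (mode, signed bp to TSS):")
print(assignments.to_string(index=False))

calls = pd.Series("up", index=assignments["region_id"].unique())
name, members = annotate.build_region_gene_sets(calls, assignments, "demo_up_regions")
print(f"\ngene set {name!r}: {members}")
# The promoter-proximal region is promoter_associated; the +30 kb region is
# enhancer_associated (no promoter overlap anywhere); the far region maps to
# whatever genes lie within 50 kb, or nothing.
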