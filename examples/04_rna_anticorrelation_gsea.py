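"""Opposing transcriptional programs of two perturbations, plus GSEA.

Simulates RNA counts for a wild type and two knockouts whose true effects on
500 shared target genes are anticorrelated (rho = -0.6), runs differential
expression for both contrasts, estimates the fold-change correlation over
genes differential in either contrast, and tests a gene set made from the
strongest KO_A responders by pre-ranked enrichment against the KO_A ranking.
"""

import json

from chromshift import enrich, pipeline, simulate

cfg = json.loads(json.dumps(pipeline.DEFAULT_CONFIG))
genome = simulate.simulate_genome(2, 2_000_000, 800, gene_length_range=(600, 1500), seed=1)
cm, truth = pipeline.build_rna_fixture(cfg, genome, seed=1)

de_a = pipeline.run_rna_contrast(cm, "WT", "KO_A")
de_b = pipeline.run_rna_contrast(cm, "WT", "KO_B")
res = pipeline.integrate_contrasts(de_a, de_b, gene_filter="union_of_DE")
print(f"true effect correlation over shared targets: {truth.rho_true}")
print(f"estimated Pearson r over union-of-DE genes : {res.pearson_r:.3f} "
      f"(p = {res.pearson_p:.2e}, n = {len(res.pairs)})")
print(f"quadrant counts: {res.quadrants}")

ranked = enrich.rank_genes(de_a["log2FC"])
up_in_a = list(de_a.index[de_a["call"] == "up"][:50])
gres = enrich.gsea_prerank(ranked, {"KO_A_up_responders": up_in_a}, n_perm=1000, seed=1)
row = gres.table.iloc[0]
print(f"\nGSEA of the KO_A-up set against the KO_A ranking: "
      f"ES={row['ES']:.2f} NES={row['NES']:.2f} p={row['p']:.3g} q={row['q']:.3g}")
# A strongly negative r reproduces the anticorrelated regulation the two
# perturbations were built with; the self-derived set must enrich at the top
# of its own ranking (ES near 1), a sanity check of the enrichment machinery.
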