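"""Threshold-filter DE tables and integrate the resulting gene sets.

Applies the two printed rules - |log2FC| >= 1 & FDR < 0.05 for knockdown
RNA-Seq, log2FC >= 0.5 & FDR < 0.05 for RIP-Seq association - then annotates
each knockdown-upregulated gene with tumor-repression and promoter-
methylation flags and quantifies one overlap hypergeometrically.
"""

from rbpkit.genesets import GeneSet, filter_de, integrate_sets, overlap_test
from rbpkit.simulate import sim_de_table

kd_table, kd_truth = sim_de_table(n_genes=2000, frac_up=0.05, lfc_effect=2.0,
                                  noise_sd=0.1, seed=3)
up_in_kd = filter_de(kd_table, min_abs_lfc=1.0, max_fdr=0.05, direction="up",
                     name="up_on_knockdown")
print(f"knockdown rule (|log2FC|>=1, FDR<0.05): {len(up_in_kd)} genes up")

tumor_table, _ = sim_de_table(n_genes=2000, frac_up=0.03, frac_down=0.08,
                              lfc_effect=2.0, noise_sd=0.1, seed=4)
down_in_gbm = filter_de(tumor_table, 1.0, 0.05, "down", name="down_in_tumor")
print(f"tumor-repressed set: {len(down_in_gbm)} genes")

methylated = GeneSet("h3k27me3", frozenset(list(up_in_kd.genes)[::2]),
                     "promoter caller output (demo: every other up gene)")
table, summary = integrate_sets(up_in_kd, methylated, down_in_gbm, down_in_gbm)
print("flag combinations among knockdown-up genes:")
print(summary.to_string(index=False))

universe = GeneSet("universe", frozenset(kd_table["gene_id"]), "all simulated genes")
ov = overlap_test(up_in_kd, down_in_gbm, universe)
print(f"up-in-knockdown vs down-in-tumor: {ov.intersection} shared, "
      f"fold {ov.fold_enrichment:.2f}, hypergeometric p {ov.hypergeometric_p:.3g}")
# Genes silenced in tumors that reappear when the protein is depleted are the
# candidates for its repressive program; the overlap test says whether that
# intersection is larger than chance.
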