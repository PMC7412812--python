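"""Permutation test: is the motif over-represented in target-gene 3'UTRs?

Simulates a transcriptome in which RIP-Seq target genes carry GCGCGGG in
their 3'UTR at rate 0.4 versus 0.1 in the background, then asks how often a
random target-sized draw from the expressed background reaches the observed
motif proportion.
"""

from rbpkit.enrichment import build_background, motif_proportion, permutation_test
from rbpkit.simulate import sim_transcriptome

utrs, targets, counts, truth = sim_transcriptome(
    n_genes=2000,
    n_targets=200,
    spike_rate_targets=0.4,
    spike_rate_background=0.1,
    seed=5,
)
background = build_background(counts, min_count=2)
result = permutation_test(targets, background, utrs, n_iterations=10_000, seed=5)

print(f"background: {result.n_background} expressed genes; targets: {result.n_targets}")
print(f"observed motif proportion among targets: {result.observed_proportion:.3f}")
print(f"null proportion: {result.null_mean:.3f} +/- {result.null_sd:.3f}")
print(f"empirical p (10,000 iterations, add-one corrected): {result.empirical_p:.2e}")
# An observed proportion ~0.4 against a ~0.1 null means the motif is far more
# common in target UTRs than a random gene draw would give - the enrichment
# signature of direct binding.
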