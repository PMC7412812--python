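# Methods

This note records the models, defaults and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Probe pool design

**Backbone.** The pool derives from the de Bruijn sequence of order 11 over
the DNA alphabet, constructed as the lexicographically least sequence by
Lyndon-word (FKM) concatenation. The construction is unique, so the design
is deterministic without any RNG; the cyclic sequence (4^11 = 4,194,304 nt)
is linearized by appending its first 10 letters, so every linear 11-mer
window is one cyclic word.

**Tiling.** 241,399 windows of 35 nt cover the linearized backbone with the
first window at offset 0 and the last flush with the end. Window starts
follow the exact integer schedule `start_i = floor(i·T/(n−1))` with `T` the
total span, giving steps of 17 (150,885 of them) and 18 (90,513) at full
scale. The maximum step is capped at `variable_length − (pool_audit_k − 1)`
so every audit k-mer occurrence of the backbone lies wholly inside at least
one window.

**Forbidden-site excision.** The SapI/BspQI recognition 7-mers GCTCTTC and
CGAGAAG (reverse complements of one another) are removed from every
variable region by substituting the center base (position 4 of 7) of each
occurrence. All three substitute bases destroy the same set of overlapping
k-mers — destruction depends only on the position — so candidates are ranked
only by constraint (a): the first base in alphabet order that creates no new
forbidden 7-mer within ±6 nt wins. If no single substitution works (never
observed at any scale tested), a two-base repair inside the occurrence is
attempted. Each occurrence appears in one or two overlapping windows; both
copies are repaired identically.

**Coverage floors and admissibility.** The audits count k-mers over variable
regions only (the constant initiation prefix would distort counts), with
multiplicity, strands as written. A 9-mer containing a forbidden 7-mer as a
substring cannot occur in an excised pool, so the 96 such 9-mers are
excluded from the 9-mer floor, which applies to the remaining 262,048; the
two forbidden 7-mers themselves are excluded from the per-set 7-mer floor.
This is the only reading under which a site-free pool can satisfy a
universal multiplicity floor.

**Patching.** Excision and the alternating A/B split leave small deficits at
full scale (18 nine-mers short of 16 pool-wide; 4 seven-mers short of 155
across the two sets). After the set split, the patch stage overwrites
expendable windows in place — windows whose every 9-mer keeps a pool count
strictly above the floor and whose every 7-mer keeps its set count strictly
above the per-set floor without them — with synthetic patch probes packing
the deficient k-mers (junction-aware, so packing never recreates a forbidden
site). In-place overwriting preserves both the probe count and the A/B
alternation; at default scale 14 of 241,399 windows (0.006%) are replaced,
against a budget of 0.1%. If a design's floors were already unmet before
excision (e.g. a single short probe), patching is skipped and the audits
report the failure honestly.

**Initiation prefix.** Each probe gets a φ2.5 T7 initiation trinucleotide
(AGA, falling back to AGG if the DNA-space junction would recreate a
forbidden site — enumeration shows AGA never can, and AGG only when the
variable region starts with CTCTTC) and is transcribed T→U. RNA length is
3 + 35 = 38 nt, within the 41-nt cap; whether the cap includes the prefix
was ambiguous and we include it.

**Not reproduced.** The published pool's secondary-structure minimization is
unspecified; an optional screen flags probes with a perfect hairpin stem
≥ 8 bp (disabled by default). 11-mer completeness is not enforced — the
source design states not every 11-mer is represented.

**Scaled-down designs.** The audit k-mer lengths are PoolDesignSpec fields
(`pool_audit_k`, `set_audit_k`) so toy designs scale them with the order
(order 5 audits 5-mers/3-mers). Toy designs need tiling redundancy
(~3× coverage) for the patch stage to have expendable windows; at exactly
1× coverage every k-mer occurrence is load-bearing and excision losses are
unrepairable at fixed probe count.

## Intensity Z-scores and PFM

Each 7-mer with at least `min_probes` (default 10) carrier probes gets a raw
score: the 5%-per-tail trimmed mean of natural-log intensities of probes
containing it, computed per set, and combined. Z-scores standardize the raw
scores across the scored 7-mer population; they are one-sided in
interpretation (only positive Z read as binding) and invariant to rescaling
all intensities. The trimmed means are computed by sorted cumulative sums
(validated against `scipy.stats.trim_mean`); a population whose raw-score
standard deviation is at floating-point noise level (≤ 1e−12 relative)
yields all-zero Z. The motif model stacks the top-N 7-mers by combined Z,
ungapped at offset 0, into a count PFM; consensus is the column argmax with
ties broken A < C < G < U. The exact scoring of the original microarray
pipeline (dinucleotide weighting, per-array normalization) is out of scope;
trim fraction, log base and support floor are exposed parameters.

An identifiability caveat the simulations make visible: 7-mers overlapping
the true motif share its carrier probes and are co-enriched — on a de Bruijn
toy pool (single motif locus) they are inseparable from it. This is assay
physics, not an artifact, and is why motif derivation aggregates top k-mers
into a PFM rather than reading the single best 7-mer.

## 3′UTR motif enrichment

The background is every gene with count ≥ 2 in at least one sample. A gene
"has the motif" if any of its 3′UTR isoforms contains an exact GCGCGGG
match (T≡U, overlapping hits counted, N never matches); a PFM mode scores
windows by log-odds against a uniform background with a threshold expressed
as a fraction (default 0.8) of the maximal score. The permutation test draws
`|targets|` genes without replacement from the background per iteration
(uniform subsets via the m smallest of n iid uniform keys, batched) and
reports `p = (1 + #{null ≥ observed}) / (n_iterations + 1)` — the add-one
correction keeps p above 1/(n+1), so extremely small tails saturate at that
floor; validation against the closed-form hypergeometric tail therefore
compares the uncorrected tail frequency within Monte-Carlo error. Genes
without a UTR are dropped with a warning and excluded from the denominator.

## Promoter H3K27me3 calling

Coordinates are 0-based half-open throughout (BED convention; 1-based input
is converted at import). Promoters are the symmetric ±3 kb windows around
each TSS, clipped at the chromosome origin; strand is recorded but does not
affect the symmetric window. Per sample, coverage is the union overlap in bp
between the window and FDR < 0.05 peaks (sweep-line merge; peaks without an
FDR value are treated as pre-filtered). A window "has a peak" at
`min_overlap_bp` ≥ 1 (any overlap — the source rule says only that coverage
was calculated, so the threshold is exposed); the ≥ 3-sample consensus is
evaluated per window, and a gene is methylated if any of its windows passes.
Calls are invariant to peak order and to splitting peaks into abutting
pieces, and monotone in added peaks and in relaxing the FDR cutoff.

## DE filters and set integration

Threshold strictness is read literally: fold-change bounds inclusive (≥),
FDR bounds strict (<). BH adjustment wraps
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`, tested against
a hand-written step-up. The RIP-Seq rule log2FC ≥ 0.5 is signed-positive by
default with an absolute-value option. Gene matching is exact string match
with optional Ensembl-style version-suffix stripping. Overlap significance
is the hypergeometric upper tail P[X ≥ |A∩B|]; fold enrichment is
(|A∩B|/|A|)/(|B|/|U|). DE estimation itself (DESeq2 and kin) is consumed as
finished tables, never recomputed.

## One-site binding fit

The model FP(c) = FP₀ + (FPmax − FP₀)·c/(K_D + c) is fit by bounded
nonlinear least squares (`scipy.optimize.curve_fit`), initialized from the
data: FP₀ at the minimum reading, FPmax at the maximum, K_D at the
concentration nearest mid-saturation; K_D is bounded positive. Degenerate
flat titrations and titrations with fewer than 5 points are rejected. The
95% K_D interval is a case-resampling percentile bootstrap (default 1,000
resamples; resamples that collapse to a single concentration or flat signal
are skipped, and the CI is omitted if fewer than 10% converge). The default
simulated truth is K_D = 47 nM with baseline 60 and plateau 160 polarization
units on the grid {0, 5, 10, 25, 50, 100, 250, 500, 1000} nM read in
triplicate, the standard plate-reader practice; at 1% (of dynamic range)
Gaussian noise this yields ~1.5% median K_D recovery error.

## Metabolomics

PQN: the reference spectrum is the feature-wise median over QC samples
(option: over all samples); each sample's quotient is the median over
features of sample/reference with zero or missing values excluded, and the
sample is divided by its quotient. PQN is idempotent and recovers pure
dilution exactly. The QC filter keeps features with CV = sd/mean (ddof = 1)
strictly below 0.25 across QC injections; zero-mean features are dropped
with a warning. Volcano selection requires both |log2FC| ≥ 0.4 — the "0.4
fold-change threshold" read on the log2 scale, with a linear 1.4-fold
reading selectable — and Welch two-sample t-test p < 0.05 on log2
intensities. A descriptive PCA score matrix (SVD of the standardized log2
table) is exported for plotting only.

## IHC scoring

Percent positivity bins: 0 only at exactly 0%; 1 below 25%; 2 on the closed
25–75% bin; 3 above 75%. The total score multiplies intensity by the percent
category (the operative published rule); the alternative sum rule is kept
because the product rule cannot produce a total of 5 even though the printed
moderate bin is 4–5 — the scheme's internal tension, documented rather than
resolved. Classification: ≥ 6 strong, 4–5 moderate, 1–3 weak, 0 null;
binary high = moderate ∪ strong. Grade association is the Pearson
chi-square without continuity correction on the binary-expression ×
grade-group (I–II vs III–IV) table.

## Synthetic data

All generators draw from numpy's PCG64 (`default_rng(seed)`) and return a
`SimTruth` record (generator name, seed, parameters, planted truth) that
serializes to JSON; identical seeds give identical outputs. What they
emulate, and what they do not:

- `sim_transcriptome` plants the motif at exact Bernoulli rates into
  motif-free (rejection-sampled) i.i.d. UTRs. Real UTRs have composition
  structure, isoform overlap and length–GC correlations; passing tests show
  the statistics are correct under exchangeability, not that real UTRs are
  exchangeable.
- `sim_peaks` places promoter peaks in exactly k samples and decoys strictly
  outside promoters on a single 1 Mb toy chromosome with disjoint windows —
  a noise-free setting in which recall and false-positive rate are exactly
  1 and 0; it does not emulate peak-boundary noise or overlapping promoters.
- `sim_de_table` produces the shape of a DESeq2 output (log2FC, Welch-t p,
  BH padj from simulated replicate means), not a count model.
- `sim_metabolites` standardizes QC noise to an exact per-feature CV so the
  25% filter has deterministic truth; dilution is purely multiplicative.
- `sim_intensities` multiplies carrier-probe intensities by a constant and
  adds lognormal noise; no saturation, spatial or sequence-composition
  effects.

## Problem sizes in the test suite

The full-scale pool design (241,399 probes) runs once per test session and
in the acceptance script, each taking seconds. Statistical validations use
10,000 permutation iterations for the hypergeometric benchmark, 200
repeats × 999 iterations for null calibration, 200 randomized instances for
the interval-overlap oracle, 500 simulations for binding-fit recovery and
2,000 null features for volcano calibration — sizes at which Monte-Carlo
error is well below the tested tolerances.

## Known limitations

- The designed pool reproduces the published pool's combinatorial
  guarantees, not its actual probe sequences (which also underwent an
  unspecified structure minimization).
- The 7-mer Z-score is a reconstruction of the cited scoring approach from
  its description; the original pipeline's exact normalization is not public
  in the text this follows.
- The permutation test treats genes as exchangeable; real enrichment
  analyses may want GC- or length-matched backgrounds, which can be supplied
  as the background list.
- The methylation caller consumes peak calls; it does not model read-level
  evidence or peak-calling uncertainty beyond the FDR column.
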