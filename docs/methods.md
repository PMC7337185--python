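# Methods

This note documents the models and procedures implemented in `pirnatk`, the
assumptions they make, the parameters that matter, and what the synthetic
data generator does and does not emulate.

## Coordinate conventions

All internal coordinates are 0-based half-open. The two 1-based inclusive
external formats — GFF3 and the 12-column tabular hit format — are converted
at the I/O boundary (`io_formats`) and nowhere else. A minus-strand hit is
encoded in the raw tabular format by `subject_start > subject_end` and made
explicit at ingestion. A read's biological 5′ end is its lowest coordinate
on the plus strand and its highest coordinate on the minus strand; this
single definition drives ping-pong overlap arithmetic and window assignment.

## TE annotation

Hits below 80% identity are removed; the boundary value 80.0% is kept (the
removal rule is a strict `< 80%`). Merging of same-family, same-contig,
same-strand hits joins two spans when they overlap or when
`len(A) + len(B) + gap < consensus_length` (strict `<`), run to a fixpoint
that always joins the first qualifying pair in sorted genomic order. For
non-nested hits this is exactly a left-to-right adjacent scan; when a short
hit is nested inside a longer one it may also bridge to an earlier
neighbour, which the fixpoint handles deterministically. The merged
insertion is the union hull; its identity is the alignment-length-weighted
mean of its hits (the weighting is a documented choice — an unweighted mean
is not distinguishable on the data the pipeline targets, but weighting is
the less surprising convention for merged alignments).

Cross-family conflicts trigger only on "full" overlap, operationalized as
containment of one span in the other or reciprocal overlap of at least 50%
of the shorter span; the higher-identity insertion wins (ties: longer span,
then lexicographically smaller family id). Partial overlaps with substantial
family-specific flanks leave both insertions standing, as two independent
insertions. The 50% threshold is configurable; some cutoff is required to
make "overlapping" and "partially overlapping" simultaneously actionable.

Completeness is the genomic hull length divided by the consensus length; a
copy is full-length at completeness ≥ 0.98. Median family length uses the
hull lengths, not summed hit lengths.

## Copy alignment and nucleotide diversity

Copies are placed back on consensus coordinates by ungapped sliding
alignment at the best Hamming-score offset (smallest offset wins ties),
gap-filling positions outside the copy. This is adequate because the data
model is substitution-only; with indels a gapped mapper would be required,
and the placement accuracy property (≥ 99% exact offset recovery at 3
substitutions per 80-nt fragment) would not transfer.

Nucleotide diversity is the frequency-weighted double sum
`π = 2 Σ_i Σ_{j<i} x_i x_j π_ij`, with `π_ij` the per-site difference over
columns where neither copy has a gap or N. Copy frequencies default to 1/n:
the pipeline annotates a single genome where each copy occurs once. With
equal frequencies the statistic equals `(n−1)/n` times the mean pairwise
difference. A copy pair with zero comparable columns (e.g. a 5′ fragment
against a 3′ fragment) contributes `π_ij = 0` with a logged warning rather
than propagating NaN; at realistic truncation levels this biases π of highly
fragmented families downward, which is flagged to the user.

## Small-RNA processing

Size windows are inclusive: 19–30 nt for TE-derived small RNAs, 23–30 nt for
piRNAs. The end-to-end matcher scans both strands of every reference for
full-length, ungapped placements with at most `max_mismatch` (default 3 for
consensus, 1 for genome) mismatches and reports the best stratum (minimum
mismatch count). Candidate generation uses the pigeonhole principle — one of
`m+1` read segments must match exactly for a placement with ≤ m mismatches —
with exact substring search or a k-mer position index (k = 11) for repeated
genome-scale scans; both routes are property-tested against an exhaustive
position-by-position scan. The pigeonhole argument is complete only for
substitution-type differences, matching the data model.

A read whose best-stratum placements all fall on one family is assigned to
it (multiple positions on the same consensus are fine); best strata spanning
two or more families cause the read to be discarded. Reads therefore
partition exactly into assigned + discarded + unaligned.

miRNA counting uses exact full-length matches to the miRNA reference in
either orientation. Exactness is a reproducibility choice; the normalized
level is counts per million miRNA reads, a cosmetic scale (ratios and all
classifications are scale-invariant). The ovary/testis fold change adds a
pseudocount of one raw read per tissue before normalization, keeping the
classification total and monotone; a family is ovary-biased at ratio > 2 and
testis-biased at ratio < 1/2. Externally computed differential-expression
classes can be supplied as a TSV instead and used downstream unchanged.

## Ping-pong signature

For one family, every sense × antisense alignment pair that physically
overlaps contributes its 5′–5′ overlap `k = (minus 5′) − (plus 5′) + 1` to a
histogram over k = 1..20. Pairs are all combinations (not capped per read);
`--collapse` first reduces reads to unique (5′ position, length, strand)
species. The z-score at overlap 10 uses the other 19 offsets as background
with the population SD; significance is z > 1.96 (one-sided 2.5%). When the
background SD is zero the signature is +∞ (significant) if the count at 10
exceeds the background mean and undefined (not significant) otherwise. The
background window K and the SD flavor are parameters; published signature
tools differ on both, so they are explicit here rather than asserted.
Calibration on synthetic nulls (uniform read positions, 2,000 reads/family)
yields a ~2–3% false-positive rate, and 200 planted pairs per family give
essentially full power — both re-measured by `scripts/acceptance.py`.

The pairs-per-piRNA metric is the overlap-10 pair count divided by the
number of piRNAs assigned to the family, reported as missing when that
number is zero.

## Cluster screen

Windows are non-overlapping 1-kb tiles anchored at coordinate 0 (a sliding
variant is deliberately out of scope; fixed tiles are the simplest
reproducible reading, and window size is a parameter). A read belongs to the
window containing its 5′ end, which prevents double counting across tile
boundaries. Detection uses pooled ovary+testis unique-read counts with the
strict rule `count > 5 per kb`; tissue classification then applies the same
rule per tissue: ovary-only, testis-only, or both, with windows that pass
only on pooled counts reported as "both" with a low-confidence flag. Counts
are not depth-normalized before the screen (raw densities); a rescaling
option exists for sensitivity analysis. TE density profiles average, per
window position, the indicator of coverage by ≥ 1 insertion of a family in
the given sex-bias class, over all windows of a tissue class.

## Statistical layer

Pearson correlations are computed among piRNA level, mRNA level, copy
number, median length and π after log10(x+1) on the count-like variables
(piRNA, mRNA, copy number); π and median length enter untransformed.
Heavy-tailed counts make raw-scale Pearson fragile, hence the transform; a
`--no-transform` switch reproduces raw-scale values. Pairs involving a
constant column are reported as undefined. No multiple-testing correction is
applied to the significance flag (per-pair p values are the convention for
this analysis); a Benjamini–Hochberg column is emitted alongside for
transparency.

The copy-number dichotomy is ≥ 20 vs < 20 copies (boundary configurable).
The Wilcoxon rank-sum test is exact by exhaustive enumeration of all
`C(n, n₁)` labelings (midranks for ties; two-sided p as twice the smaller
tail, capped at 1) whenever both groups have ≤ 10 observations, and the
normal approximation with tie correction otherwise.

## Synthetic data generator

The generator is the package's study design, not a test fixture. From one
integer seed it produces byte-identical outputs.

*Genome*: i.i.d. uniform background nucleotides across the configured
contigs. Each TE family gets a random consensus; each copy is the consensus
or a truncated fragment (retained fraction uniform on
[min_truncated_fraction, 0.98), anchored at a uniformly chosen end —
mimicking 5′-truncated non-LTR copies and degraded elements without
modelling mechanism), mutated i.i.d. at the family's per-site divergence
(uniform over the three alternative bases, no indels), and inserted at a
uniform non-overlapping position on a uniform strand. Copies of the same
family are additionally kept at least one consensus length apart, so merged
annotations correspond one-to-one with planted copies — a property of the
generator chosen to make copy-number recovery exactly checkable. Planted
piRNA-cluster windows are reserved 1-kb tiles of plain background sequence
(unique by construction at piRNA read lengths) with an assigned tissue
activity. A dedicated scaffold carries the fixed 50-sequence miRNA
reference set and is excluded from TE annotation, keeping the normalization
denominator clean.

*Hit tables*: since running the similarity search is out of scope, the
generator emits the hit table directly from the truth, with true per-copy
identities; a configurable fraction of copies is reported as two overlapping
partial hits to exercise the merger.

*Small-RNA libraries*: miRNA reads are exact copies of the reference set;
TE reads have uniform lengths in [23, 30] and are sampled from planted
copies. A configurable ping-pong fraction of each family's budget is emitted
as sense/antisense pairs with exactly 10-nt 5′ overlap on the consensus
frame; remaining reads get uniform positions and strands. Cluster reads are
drawn uniformly inside active planted windows. Every read carries a
provenance row.

*mRNA counts*: negative-binomial draws whose log10 mean is
`intercept + effect·log10(copy number)`; the NB size parameter controls
overdispersion with the Poisson limit at infinity. For the statistical
layer, a model-based trait table (`simulate_trait_table`) plants the full
dependency web — piRNA output increasing with mRNA level (itself driven by
copy number) and family length, decreasing with π — with effect sizes
(mRNA 0.6, length 0.4, π −4.0 per unit, noise SD 0.25 on log10 scale) chosen
once as plausible for gonadal TE regulation at ~100 families; sequence-level
simulation would add nothing to what this layer tests.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: indels and rearrangements (annotation of
real, indel-riddled copies needs a gapped aligner), sequencing errors and
quality, adapter contamination, rRNA/tRNA/degraded-mRNA contamination of
small-RNA libraries, nested TE insertions (copies never overlap, so the
cross-family resolution step is exercised only by unit tests), non-uniform
genomic background (real cluster detection contends with repetitiveness the
uniform background lacks), and transcription-unit structure of clusters.

## Problem sizes and numerical choices

The default simulated study uses a 750-kb genome, 10 families (copy numbers
5–30, divergence 0–0.12, consensus 0.8–3 kb), ~5,000 reads per tissue; the
calibration analyses use a 2-Mb genome with 20 families (copy numbers 5–60,
divergence ≤ 0.1) and 100 simulated families/windows per calibration — sizes
at which every property is measurable in seconds while preserving the
regimes of interest. Ties in sliding alignment go to the smallest offset;
degenerate inputs (empty groups, constant vectors, zero denominators,
windows with no reads) raise explicit errors or are reported as missing, as
documented per function.
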