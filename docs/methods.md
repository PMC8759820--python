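# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind strainkit, in the order the pipeline runs them.

## Element locating

A "complete" element copy is defined operationally: a local alignment of
the full family sequence against the assembly reaching both

* identity ≥ `min_identity` (default 0.95) — matches divided by alignment
  columns, so gaps count against identity (the BLAST-style statistic), and
* query coverage ≥ `min_coverage` (default 0.95) — aligned query bases
  divided by query length.

The coverage filter is what excludes solo LTRs and fragmented copies; the
defaults mirror the thresholds commonly used for complete-Ty annotation of
yeast assemblies.

The production engine anchors exact 15-mers of the family sequence in the
contig (both strands), groups anchors by diagonal with a tolerance of
max(30, 5% of the query length), splits groups where consecutive anchor
positions jump by more than 500 bp (fragmented copies are deliberately not
chained into one hit), and aligns the full family sequence against each
implied region with edlib in infix mode. The resulting semi-global path is
then reduced to its maximal-scoring contiguous segment under a BLAST-like
scoring (match +2, mismatch −3, gap −4 per column; a one-dimensional
Kadane pass over the CIGAR columns). This last step matters: without it, a
~90%-truncated copy can keep nominal coverage 1.0 by letting its missing
tail "align" into the flanking sequence as mismatches, diluting identity
to just above threshold. With local trimming, truncation reduces coverage,
as it should.

Overlapping candidates (any family, any strand) are resolved to one
element per location: among hits overlapping by more than 50% of the
shorter interval, the highest identity wins; ties break to the longer
alignment, then the lexicographically first family name.

**Reference scanner.** `locate_te_exhaustive` re-derives the loci with a
full Smith–Waterman dynamic program (linear gap penalty, numba-compiled)
over every contig × family × strand, tracking per cell the matches,
columns and start coordinates of the best local alignment ending there.
Per target end position the maximal-scoring cell is recorded; candidates
are reduced with the same overlap rule and only then threshold-filtered,
so the scanner reports peak alignments exactly as a BLAST-style search
would. The scanner shares no code with the anchored path beyond the
overlap rule and serves as its oracle: on planted 50–100 kb instances the
two agree on counts, strands and intervals to within ±5 bp (boundary
slack exists because distinct optimal alignments of equal score can trade
a terminal match for an indel).

"Chromosome-scale" filtering keeps loci on contigs of at least a given
length; 100 kb is a reasonable default for yeast-sized genomes, and the
threshold is exposed because no universal value exists.

## Location conservation

Each locus is extracted together with 1,500 bp of upstream and downstream
genomic context (clamped at contig ends, with clamp flags recorded);
minus-strand loci are reverse-complemented so elements are always in
library orientation. Two flanked loci represent the same location when
they align with ≥ 95% identity and ≥ 99% query coverage. Coverage is
directional, so both query directions are tried and either passing
suffices — this restores the symmetry a distance measure needs and is also
what makes clamped flanks unproblematic (the shorter sequence as query
reaches full coverage). Only same-family pairs are compared: a cross-family
pair cannot reach 99% coverage over a full-length element plus flanks.

The per-pair matching is built greedily by descending identity with each
locus used at most once (ties break to the smaller coordinate pair).
Optimal bipartite matching differs only in contrived configurations; the
greedy choice is deterministic and transparent.

## Distances, trees, concordance

The strain distance is the Jaccard distance over location sets,
d = n_distinct / (n_a + n_b − n_shared), a true metric on sets; the
averaged alternative 1 − 2·n_shared/(n_a+n_b) is available behind a flag
(`method="average"`). Neighbor joining is the classic Q-criterion
agglomeration with ties broken to the lowest index pair and negative
branch lengths clamped to zero (logged). NJ is exact on additive matrices,
which the test suite exercises with random trees of up to 8 leaves via the
patristic-matrix round trip.

`snp_distance` counts single-base mismatches inside gap-free blocks:
21-mers that occur exactly once in each assembly and are shared define
anchors; anchors are chained colinearly per contig pair (longest increasing
subsequence), maximal same-diagonal runs delimit blocks, block interiors
are compared position by position, and the chain's terminal blocks are
extended to the sequence boundaries. Where the diagonal changes — element
insertions or excisions — the intervening window is skipped and contributes
nothing. On simulations without element gain/loss the genome stays on one
diagonal and the count equals the planted truth exactly; with indels
present, substitutions falling inside the (typically tens of bp wide)
anchor-free windows are missed, a deliberate trade the gap-free-block rule
makes to avoid ever counting alignment artifacts as SNPs.

Concordance between the two signals is the Pearson correlation of the
shared-location fraction (union-normalized) with the SNP count across all
strain pairs (Spearman behind a flag); it requires ≥ 3 pairs and nonzero
variance in both variables.

Robinson–Foulds distances are computed from canonical bipartition sets
(the side not containing the lexicographically first leaf), with trivial
splits and the duplicate split of a degree-2 root discarded; dendropy is
used in the tests as an independent cross-check, never in the
implementation.

## Copy number and ΔΔCt

Tandem copies are counted as non-overlapping full-length matches of the
marker genome-wide through the same locating engine, so the count is
strand-agnostic and tolerant of per-copy divergence up to the identity
threshold. The comparative-Ct reduction assumes perfect doubling per
cycle (efficiency 2): ΔCt = mean Cq_target − mean Cq_reference per sample,
ΔΔCt = ΔCt_sample − ΔCt_calibrator, fold = 2^(−ΔΔCt). Replicate scatter
is propagated as the root sum of squared standard errors of the four Cq
means and reported as an interval on the fold (2^(−ΔΔCt ± sd)). The
calibrator's copy number follows as assembly copies / fold.

The end-to-end recovery study plants a known truth (sample 8 copies,
calibrator 16), adds Gaussian Cq noise of sd 0.2 cycles to triplicate
reactions, and averages folds over six independent synthetic biological
replicates before inferring — the replicate structure a bench comparison
would use. With sd 0.2 and triplicates a single table leaves ~17%
probability of a >25% fold error (sd of ΔΔCt ≈ 0.2·√(4/3) ≈ 0.23 cycles);
averaging six replicates brings the inference comfortably inside 25%.

Locus dissection reports full-length matches of each gene query in
coordinate order, copies of the same gene numbered by position, and
pairwise substitution counts from gap-free comparison of equal-length
copies (free-end-gap alignment otherwise; gaps excluded from the count,
since the question is substitutions, not indels). Copies sharing derived
mutations then cluster by minimum pairwise count, which is how a
duplication order is read off a tandem paralog array.

## Arch profiles

Arch coordinates are 1-based inclusive on the protein (the convention of
the upstream predictors); internally everything is 0-based half-open. The
cumulative score of residue i is the sum of the scores of all arches
covering i, so the total profile mass equals Σ score·(arch length) — an
invariant the tests assert. Projection onto an MSA places each residue's
score at its alignment column and scores gap columns exactly 0; row order
follows the MSA. Profile differences are reported as magnitudes only — no
significance classification is attached, because no principled threshold
for "increased amyloidogenicity" exists at this level.

## Circular utilities

Anchored rotation searches both strands of the doubled sequence (so
matches wrapping the origin are found) with an edit-distance budget of 5%
of the anchor length by default; if the best match is on the minus strand
the molecule is reverse-complemented first. The anchor-free fallback is
the lexicographically minimal rotation (Booth's algorithm, linear time),
checked against the all-rotations sort in the tests.

Inversion-isoform interconversion requires the repeat to occur exactly
twice in inverted orientation; the inverted segment spans from the start
of the first repeat copy to the end of the second, which leaves the repeat
content unchanged (the copies are inverted images of each other) and makes
the operation an involution. A circle has two candidate segments; the
shorter is inverted by default (the unique-region convention of 2-micron-
like plasmids), the longer behind a flag.

## The simulator

The simulator's role is to make every downstream claim checkable: it
evolves genomes along a known rooted tree and emits the complete truth —
per-strain element loci labelled with ancestral locus ids shared exactly
by orthologous placements, a per-branch gain/loss event log, and true
pairwise SNP counts.

Model: a random ancestral background sequence (default 100 kb) carries
full-length element copies (default 8, from a library of 2 synthetic
random ~1 kb families) at insertion points kept ≥ 3,000 bp from contig
ends and ≥ 3,200 bp apart, so flank extraction downstream is never clamped
and a flank never contains a neighbouring element. Along each branch of
length b: every site (background and element alike) substitutes with
probability `mutation_rate`·b, uniform over the three alternative bases —
a Jukes–Cantor-style model with branch lengths in substitutions/site;
gains arrive as Poisson(`te_gain_rate`·b) insertions of a random family
and strand at uniformly chosen valid points; each existing copy is lost
with probability 1 − exp(−`te_loss_rate`·b), excised cleanly with no scar.
There are no background indels, so true SNP counts are well defined
position by position: background positions always align, and element
positions align between strains carrying the same ancestral locus id.

What the simulator does *not* emulate — and what passing tests therefore
do not demonstrate about real data: solo-LTR formation and LTR
recombination, target-site preference and duplications, nested insertions,
segmental duplications and aneuploidy, subtelomeric repeat turnover, and
assembly error. The simulator validates the computational pipeline, not
the biology of any particular genome.

`make_tandem_array` builds a single contig with exactly n marker copies
separated by random spacers; its `divergence` parameter plants exactly
round(rate·length) substitutions per copy — a hard per-copy bound rather
than a binomial draw, so a "3% diverged" array is guaranteed to stay above
a 95% identity threshold and the constructed copy number is exact by
construction.

## Validation study conditions

The studies in `strainkit.validation` fix these conditions:

* **Locator vs oracle**: 50 instances, 50–100 kb backgrounds, one 800 bp
  family; each instance plants one exact copy, usually one diverged copy
  (≤ 3%, minus strand) and often one 85–92% truncation that must be
  rejected by both engines.
* **Tree recovery / concordance**: five strains on
  `((A:0.006,B:0.006):0.007,(C:0.006,(D:0.006,E:0.006):0.007):0.007)`,
  genome 150 kb, 12 ancestral copies, gain 1800 and loss 90 per unit
  branch length, 20 replicate seeds. These values come from a power
  analysis rather than trial: at the equilibrium copy number gain/loss
  = 20, location-turnover events accrue at ≈ gain + loss·copies ≈ 3600
  per unit branch length, so each internal branch expects ~25 events —
  the signal needed for a distance built from ~20 locations per strain to
  resolve both internal edges in ≥ 90% of replicates — while the deepest
  leaf pair stays near 3.3% divergence, keeping conserved flanked loci
  above the 95% identity threshold with several standard deviations of
  margin, and the equilibrium copy number stays well below the
  spacing-limited genome capacity (~45).
* **SNP exactness**: three strains, 50 kb, no gain/loss (indel-free), five
  seeds; the count must equal truth exactly, symmetrically.
* **CNV**: array sizes {0, 1, 2, 8, 16} at 3% per-copy divergence; ΔΔCt
  closed forms at ΔΔCt ∈ {0, 1, −2}; the noisy-inference study described
  above.
* **Arch / circular**: 50 random arch sets against direct summation, 20
  random gappy projections, 100 random rotations against brute force, 20
  random inversion involutions.

All randomness derives from a single master seed; identical seeds
reproduce every number bit-exactly.

## Numerical and degenerate-input choices

* Thresholds are inclusive (≥) everywhere.
* edlib alignments use the first reported optimal location; equal-score
  optima can shift interval boundaries by a few bases, absorbed by the
  ±5 bp tolerances.
* An assembly with zero contigs yields an empty locus list (not an
  error); all-N contigs are skipped with a logged warning.
* A strain pair with no element locations at all has no defined distance
  and raises.
* NJ clamps negative branch lengths to 0 and logs; Q-ties break to the
  lowest index pair, making output independent of label order up to ties.
* Cq values must be finite and positive; a sample lacking reference-gene
  rows is reported by name.

## Known limitations

* The locator is not an annotator: it finds copies of the provided family
  sequences and nothing else, and reports one element per location, so
  overlapping real elements (rare, but possible with nested insertions)
  collapse to the best hit.
* `snp_distance` is a desk-scale anchor-chain method; for multi-megabase
  assemblies with segmental duplication a dedicated whole-genome aligner
  is the right tool, and regions without unique anchors are silently
  skipped.
* The conservation call degrades gracefully but inevitably as divergence
  approaches the identity threshold (~5%); beyond ~4% pairwise divergence
  marginal loci start failing, which biases distances upward for the most
  distant pairs.
* ΔΔCt assumes equal amplification efficiency of target and reference;
  efficiency-corrected quantification is out of scope.
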