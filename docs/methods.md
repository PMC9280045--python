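# Methods

This note documents the statistical procedures woxkit implements, the
defaults it ships, the numerical choices that affect outputs, and what the
synthetic-data generators do and do not emulate.

## Codon-usage statistics

Codons are counted in frame 0 over whole CDS records (lengths must be
multiples of 3); triplets containing non-ACGT characters are skipped and
tallied separately. Stop codons form their own family (TER, k = 3) and
participate in every per-codon statistic, as codon-usage tables
conventionally print them. For a synonymous family of size k with counts
X_i, RSCU_i = X_i·k/ΣX and RFSC_i = 100·X_i/ΣX, so within any observed
family Σ RSCU = k, Σ RFSC = 100 and RFSC = RSCU·100/k identically. A family
never observed in a gene set is reported as undefined rather than zero.

Bias classification uses RSCU against 1 with a 1e-9 tolerance on computed
values; when classifying already-rounded published tables the printed
two-decimal values are compared verbatim (a printed 1.00 is "no bias"), with
no re-rounding of our own.

The high-frequency rule is RFSC > 60 (strict) or RFSC ≥ 1.5·(100/k)
(inclusive). The inclusive 1.5× boundary is forced by published usage
tables that mark codons sitting exactly at 1.5× the family average (e.g. an
RFSC of 37.50 in a four-codon family); no analogous boundary case pins down
the 60% clause, so strictness there is a documented choice. Single-codon
families (Met, Trp) always have RFSC 100 and are excluded from
classification — published tables never mark them.

Host comparison expresses usage as occurrences per 1,000 codons; ratios are
unit-free, so this scale cannot affect classification. The similarity band
is inclusive at both ends: a ratio ≤ 0.50 or ≥ 2.00 is divergent. A codon
used by the gene set but absent from the reference is divergent with an
undefined ratio; absent from both, undefined. Host ranking sorts by
divergent-codon count, breaking ties by the mean |log2 ratio| over non-stop
codons with defined ratios and then by label; the tie-break is our own
deterministic convention, since count alone cannot order hosts that tie.

### The transcribed worked-example tables

The packaged fixture TSVs transcribe a published four-species RSCU/RFSC
table and its companion frequency-ratio table at their printed two-decimal
precision. Three stop-codon cells of the *J. curcas* column are internally
inconsistent in print (RSCU and RFSC cannot both be right; they appear
transposed) and carry an `anomaly` flag. An audit test checks
|RFSC − RSCU·100/k| on every other cell and currently reports sixteen
further inconsistent cells, all in the *M. esculenta* RSCU column, whose
printed values in several two-codon families contradict the RFSC column
(the RFSC column sums to 100 per family and agrees with the table's
high-frequency marks, so the RSCU cells are the corrupt ones). The fixtures
deliberately keep the printed values: the classification counts the tables
are used for reproduce exactly as published, and the audit documents the
defect rather than silently repairing it.

## Protein physicochemistry

Molecular weight uses average residue masses (free amino-acid mass minus
water) plus one water (18.01524 Da); X and other non-standard residues are
rejected rather than approximated. Net charge at a given pH is the
Henderson–Hasselbalch sum over positive groups (N-terminus, H, K, R) and
negative groups (C-terminus, D, E, C, Y); cysteine is treated as ionizable
(reduced form). The pI is found by bisection on [0, 14] to a 1e-3 pH
tolerance — the charge is strictly decreasing with opposite signs at the
interval ends, so the root exists and is unique. The default pKa set is
Bjellqvist-style as used by the ExPASy lineage; because published pI values
depend on the exact table version, the set is configuration, not ground
truth, and alternatives can be passed in.

The instability index is (10/L)·Σ DIWV(x_i, x_{i+1}) over consecutive
residue pairs with the Guruprasad dipeptide weights; II ≥ 40 is classed
unstable (boundary on the unstable side). The aliphatic index is
X_A + 2.9·X_V + 3.9·(X_I + X_L) in mole percent, and GRAVY is the mean
Kyte–Doolittle hydropathy. The constant tables (masses, DIWV, hydropathy)
are taken from biopython's data modules rather than re-shipped.

## Phylogeny

Distances on protein alignments use pairwise gap deletion: for each pair
only columns where neither sequence is gapped are compared; p = mismatched
fraction, and the Poisson correction is −ln(1−p). The default model is the
p-distance; a pair with no comparable column, or a saturated pair under
Poisson, is an error naming the pair.

Neighbor joining is the Saitou–Nei algorithm: join the pair minimizing
Q(i,j) = (n−2)·d(i,j) − r_i − r_j, with the standard branch-length and
distance-update formulas. Two choices make the output a pure function of
the distance matrix: Q ties (within 1e-12) are resolved toward the
lexicographically smallest pair of cluster labels (each cluster labelled by
its smallest leaf), and candidate pairs are scanned in sorted order.
Negative branch lengths — possible for non-additive inputs — are clamped to
zero with the deficit moved to the sister branch, preserving the joined
pair's path length; this follows common NJ practice, changes printed
lengths but never the topology. For additive matrices the algorithm
reproduces the generating tree's path lengths exactly (verified to 1e-9
against an exhaustive least-squares topology search on up to 8 taxa).

Bootstrap supports resample alignment columns with replacement; an internal
edge's support is the percentage of replicate trees containing the same
leaf bipartition. Replicates that leave some pair with no comparable
column are dropped and logged. Supports are attached as internal node
labels in Newick output.

Clade assignment labels each non-anchor gene with the clade of its nearest
anchor (minimum distance over that clade's anchors); the margin is the
second-best clade's distance minus the best, and a zero margin yields
"ambiguous" rather than an arbitrary choice. Percentage summaries round
half away from zero to one decimal.

## Annotation

Gene models keep GFF3's native 1-based inclusive coordinates at every
interface; segments are stored sorted by genomic start regardless of
strand, and minus-strand CDS is reverse-complemented once as a concatenated
whole. One isoform per gene is assumed (the first mRNA is used otherwise).
Genes spanning more than 3,000 bp are flagged long; the threshold is
exclusive at exactly 3,000.

Promoters are the up-to-2,000-bp region ending immediately before the first
CDS base, read 5'→3' in gene orientation; a contig edge yields a shorter
region flagged truncated, and a start codon at the contig edge is an error.
Motifs are IUPAC consensus strings with a required stress / hormone /
growth category. Scanning reports every match on both strands, overlaps
included, using lookahead matching; a palindromic consensus therefore
reports one hit per strand at the same position. Positions are 1-based on
the promoter fragment. No position-weight-matrix scoring or p-values are
attempted — the scanner is a deterministic consensus matcher, and the
curated motif dictionaries of online promoter-annotation services are not
redistributed; a small demo table ships for tests and examples.

## Expression

The comparative Ct method uses two reference genes: per sample,
ΔCt = mean target Ct − mean over the references of their mean Ct (the
arithmetic mean of Ct equals the geometric mean of linear quantities);
ΔΔCt is against a calibrator sample, fold = 2^−ΔΔCt, with amplification
efficiency fixed at 2.0 (no efficiency correction). The construction makes
fold changes invariant to per-sample plate shifts and pins the calibrator
column at exactly 1. Significance is a two-sided Student's t-test on
replicate-level ΔCt against the calibrator at α = 0.01, with no
multiple-testing correction; single-replicate samples get a fold but a
skipped, flagged test. Heatmap transforms are log2(x+1), optionally
followed by per-row z-scoring; constant rows get z = 0 and are flagged
instead of dividing by zero.

## Synthetic data

All generators are pure functions of (parameters, seed); one global seed is
expanded into per-generator substreams via fixed spawn keys, so adding a
generator never changes existing outputs. What they emulate, and what they
do not:

- **CDS sets**: iid amino acids (uniform over 20) with per-family codon
  probabilities (fixed, or Dirichlet-drawn); start and stop codons added,
  internal stops impossible by construction. No amino-acid composition
  bias, no GC gradients, no length distribution realism.
- **Alignments**: a uniform root sequence evolved down a given tree with
  Poisson(rate·branch length·columns) substitutions per branch, uniform
  replacement over the other 19 residues. Deliberately not an empirical
  substitution matrix — sufficient for distance/NJ recovery testing, not
  for realistic protein evolution; no indels, so simulated alignments are
  gap-free.
- **Gene bundles**: alternating-strand, non-overlapping 2–4-exon genes with
  UTRs and 100–800 bp introns on one contig, with exact truth coordinates
  and CDS. No repeats, isoforms, or nested genes.
- **Promoters**: motifs planted at disjoint, non-adjacent slots on random
  strands over a configurable background alphabet. With a background
  disjoint from the motif's letters and their complements (an A/T-only
  motif on a C/G background), scan counts recover the planted counts
  exactly; on an ACGT background chance matches are expected and the truth
  records planted counts only.
- **Ct tables**: target Ct = ref_ct + baseline − log2(fold) + N(0, sd),
  references flat at ref_ct + noise, default triplicates, two reference
  genes. No inter-run calibrators, efficiency variation, or outlier wells.

Because of these simplifications, passing tests demonstrate algorithmic
correctness and statistical recovery under the stated models, not
performance on real genome releases.

## Problem sizes and tolerances used in the test suite

Convergence tests size their simulations so the asserted tolerance is a
>3.5σ event under the binomial/normal sampling error (about 5×10^5 codons
for RSCU-within-0.05; 400 genes × 1,000 codons for RSCU → k·p). The NJ
acceptance check runs 100 random additive matrices on 4–8 taxa against an
exhaustive topology enumeration (10,395 topologies at 8 taxa) with an
ordinary-least-squares residual oracle. Fold-change recovery uses 200
seeded Ct tables at noise sd 0.05 and asserts a median |log2 error| below
0.1. Bootstrap examples in tests use 20–25 replicates for speed; the
pipeline default remains 1,000.

## Known limitations

- Family identification (HMM/BLAST searches, domain verification, naming)
  is out of scope: curated gene sets are inputs.
- Alignments are inputs; no aligner is wrapped.
- The NJ implementation targets gene-family scale (tens of taxa), not
  thousands; it is quadratic-per-join without heuristics.
- Published pI/MW values can only be reproduced given the same sequences
  and constant tables; the defaults are documented, not canonical.
- Expression heatmap scaling conventions differ between studies; both
  shipped transforms are explicit, and neither claims to match any
  particular figure.
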