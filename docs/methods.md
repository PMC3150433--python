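# Methods

## Matrix model and coordinates

A supermatrix is a taxa-by-columns character matrix over nucleotides,
IUPAC ambiguity codes, `-` (gap) and `?` (missing). Internally all
coordinates are 0-based half-open; NEXUS I/O converts to and from the
format's 1-based inclusive ranges, including `a-b\3` step notation.
Gene fragments are charsets that are pairwise disjoint and a whole
number of codons; within a fragment the first column is codon position
1, and the reading frame is fragment-local. Rather than re-deriving the
frame after every operation, each matrix carries an explicit per-column
codon position and an explicit list of codon column triples; slicing,
masking and shuffling remap these, so a column never silently changes
codon position and degeneracy operations keep working on derived
matrices (including shuffled ones, whose codons are no longer
contiguous).

When the exclusion mask removes part of a codon, the surviving columns
are kept (so exactly `|mask|` columns are removed) but their cells are
set to `N` and the codon is detached from the codon map. The
alternative — re-framing the remainder — would silently change the
codon semantics of downstream recodings. Whether the original study's
2,313-column mask removed whole codons is not stated anywhere we can
check, so this conservative convention is ours.

`'?'` and `-` are both treated as missing for counting purposes but
preserved verbatim on output.

## degen1

Synonymous families partition the 61 sense codons: one family per amino
acid except serine, split into `TCN` and `AGY` boxes (no single
substitution interconverts them, and their difference remains visible
after recoding). The degen1 image of a family is the per-position IUPAC
union over its codons; every member maps to that image. Leucine
(`YTN`) and arginine (`MGN`) keep their full six-codon families even
though those images overlap Phe (`TTY`) and Ser2 (`AGY`) — this
over-degeneration is the published behaviour of the coding and is kept
bit-compatible.

Conventions the published description leaves open, decided here:

- Stop codons map to `NNN` with a logged warning; in-frame nuclear
  coding data should be stop-free.
- Codons containing `-` or `?` map to `NNN`.
- Ambiguous codons are resolved conservatively: if every resolution
  yields the same image it is emitted, otherwise `NNN`. Family images
  themselves (e.g. `YTN`, whose resolutions span Leu and Phe) are fixed
  points, which is what makes the map idempotent — a property the test
  suite checks over the whole symbol space.

The fourfold-synonymous mask keeps a codon's third position only when
every resolution of its first two positions gives an amino acid in
{Ala, Gly, Pro, Thr, Val}; Leu/Arg/Ser codons in fourfold boxes are
excluded because their families are sixfold.

## Character sets

`LRall1` membership is "potential synonymous change": a first-position
column qualifies if at least one taxon's codon there has at least one
ambiguity resolution translating to Leu or Arg; all-gap or all-missing
codons never trigger membership. `noLRall1nt2` and `LRall1nt3` are
complements by construction, so their union is always the whole matrix.
Degenerate named sets (`nt3_degen1`, `LRall1nt3_degen1`) apply degen1 on
the full codon context first and slice afterwards; LR membership for
`LRall1nt3_degen1` is judged on the raw codons, since degeneration
destroys the distinction it encodes.

Rate bins keep fragments in rank order (rank 1 = fastest nonsynonymous
rate) and choose contiguous split points minimising the maximum
deviation of bin character counts from `total/k`, ties toward the
earlier split. The source study reports its bin outcomes but not its
balancing algorithm, so explicit rank ranges are accepted as an
override (`explicit_bins`).

## Subsampling

Column shuffling is a single Fisher-Yates pass of numpy's PCG64
generator; repeating a shuffle thousands of times, as the original
workflow did, yields the same uniform distribution over permutations,
so one recorded seed suffices for auditability. Complementary splits
cut the shuffled matrix into consecutive blocks of `floor(f_i * n)`
columns with the remainder in the last block; `(seed, fractions,
replicate_id)` fully determines the output, and a JSON manifest records
per-block column provenance.

## Support accounting

Trees are reduced to informative bipartitions with attached bootstrap
percentages; mirror bipartitions (the two children of a rooted tree's
root) merge keeping the larger support. "Match" is bipartition identity
after restricting the reference to the candidate's taxa — not mere
compatibility — because on a fixed taxon set a non-matching informative
bipartition of a binary tree necessarily conflicts with some reference
clade. Following the source tables' footnotes literally, a candidate
node conflicts when its support reaches the reporting threshold (50%)
and it matches no reference node whose own support is strong (80%);
strong conflict additionally requires the candidate's support to be
strong. All three thresholds (75% single-gene, 80% strong, 50%
reportable) are arguments.

A taxon counts as missing for the utility correction iff its fragment
sequence is 100% missing symbols; the utility statistic is otherwise
exactly the formula in the README. The utility-vs-rate trend is
ordinary least squares with coefficient standard errors
(scipy `linregress`).

## Composition

Base composition is computed over determinate A/C/G/T sites only, in
percent; a taxon with no countable sites is flagged undefined and
excluded from distances with a warning. Euclidean distances treat the
four percentages as independent characters (percent scale, so two pure
disjoint compositions are sqrt(2)*100 apart). The composition diagram
defaults to UPGMA (average linkage, deterministic lowest-index
tie-breaking) with neighbor joining available; the construction method
of the diagram this emulates was never stated, and UPGMA is the
conventional choice for composition dendrograms. For
`nt3_4foldsynon` input, `N` cells are excluded exactly like missing
data.

## Indel screen

Candidates are maximal `-` runs per taxon per fragment; runs with
identical bounds merge. The high-quality filter keeps events shared by
at least 2 taxa (configurable) with no partially overlapping gap run in
any other taxon; containment with different bounds counts as
staggering. `?` runs never participate, so terminal missing data cannot
masquerade as deletions. Survivors of one pass are pairwise
non-overlapping, making the filter idempotent. The original tally of
19 high-quality indels involved manual judgement of "relatively
unambiguous alignment" that a mechanical filter cannot fully encode;
the corresponding acceptance check therefore uses a generous band and
emits the per-group table for audit.

## Synthetic data generator

The simulator creates the contrasts the toolkit must detect, not a
realistic mutation-selection process. Branch lengths are expected
nonsynonymous substitutions per codon; along each branch a codon
changes family with probability `1 - exp(-b)` (new amino acid uniform
over the other families) and is synonymously re-drawn within its family
with probability `1 - exp(-mult * b)`, weighted by the lineage's
third-position bias. Each site carries a neutral third-position allele
that only synonymous events update; nonsynonymous events re-use it when
the new family allows, so with `mult = 0` fourfold third positions are
invariant across the tree — the degenerate limit the tests exploit.
Bias applies on a branch when all its descendant tips belong to one
group, producing convergent composition within groups that crosscut the
tree.

Default study-like conditions, chosen once: 24 taxa on a birth-death
tree scaled to root-tip depth 0.4 nonsynonymous substitutions per
codon; 12 fragments of 60 codons; synonymous:nonsynonymous rate ratio
10 (synonymous branch lengths in the motivating data are several-fold
longer than degenerate ones); two interleaved bias groups with
GC-rich (5/45/45/5%) versus AT-rich (45/5/5/45%) third-position
targets; one fragment with a quarter of taxa missing. The acceptance
script runs at these sizes; they are comfortably large enough for the
rank-correlation and clustering contrasts to be stable across seeds.

What the generator does not emulate — among-site rate variation,
selection on codon usage, alignment error, within-fragment rate
heterogeneity — limits what passing tests show about real data: they
validate the bookkeeping and the direction of the synonymous-bias
mechanism, not inference accuracy on empirical matrices.

## Known limitations

- Maximum-likelihood tree search and bootstrapping are out of scope;
  support values are inputs, never computed here.
- The NEXUS writer is sequential-only (no interleaving) and does not
  emit MrBayes-dialect commands.
- The published 80-taxon supermatrix cannot be redistributed with the
  package; the two acceptance checks that census it require the file to
  be supplied at `data/pone.0023408.s006.nex`.
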