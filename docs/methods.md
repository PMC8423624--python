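# Methods

## Data model

A genome is an ordered, stranded list of genes per chromosome (or
scaffold — the two are treated identically: adjacency is never inferred
across sequence boundaries, so fragmentation can only break adjacencies,
never invent them). Every gene carries exactly one ortholog-family label;
the pipeline consumes families, it does not infer them. Coordinates are
1-based inclusive; only the ordering of start positions is ever used
downstream, so the off-by-one convention cannot change any result.

## Marker genes

A family is a usable gene-order marker when it is present in every species,
has exactly one copy in every unduplicated species, and one or two copies in
every species descended from the whole-genome duplication (WGD). Markers
fall into three copy-number classes (single everywhere; two copies in every
duplicated species; mixed). Requiring presence in all species is the
default because a family absent from one genome contributes no comparable
order information there; `min_species_presence` relaxes this for exploratory
use, still rejecting illegal copy numbers wherever the family occurs.

## Adjacencies

After deleting all non-marker genes, each pair of consecutive genes on a
chromosome yields one character: the unordered pair of their families.
Characters are unoriented by default — relative strand is not part of the
pair identity — because breakpoint counting needs only co-linearity of
neighbours; signed characters (same/opposite relative orientation) are
available behind `signed=True` for users who want inversion breakpoints
within conserved neighbourhoods to count. Tandem neighbours from the same
family cannot be expressed as a pair of distinct families and are skipped
(counted in the log). In duplicated genomes, presence is the union over
copies: the adjacency exists if any copy pair realises it, matching how a
single pre-WGD adjacency should be scored in a doubled genome.

## Normalized breakpoint distance

For two genomes the distance is the fraction of the smaller genome's
adjacencies (after removing characters masked as missing in either genome)
that do not occur in the other. Normalising by the smaller set makes the
measure symmetric and robust to unequal adjacency counts from assembly
quality or WGD. When the two sets are exactly equal in size, the two
normalisations can differ by less than 1/|A|; the implementation averages
them, making the function fully symmetric. An empty scorable set is an
error, not a zero.

## WGD subgenome masking

Reciprocal loss of WGD duplicates can delete the two members of an
ancestral adjacency onto *different* duplication-derived chromosome copies,
mimicking a rearrangement that never happened. Given user-supplied
subgenome labels (copyA/copyB per chromosome of each duplicated species),
an absence is recoded to *missing* when the two families' retained copies
sit exclusively on chromosomes of opposite labels. Missing states are
excluded from both the numerator and denominator of the distance and are
free under Dollo scoring (below). Without labels the unmasked analysis runs
as-is; in the simulations the unmasked analysis reaches the same
conclusions because the WGD-induced changes are shared by all duplicated
lineages.

## Distance trees and bootstrap

Neighbor joining is the standard Saitou–Nei agglomeration; UPGMA is
size-weighted average linkage; both break criterion ties by the
lexicographic order of cluster labels (the smallest leaf name per cluster),
so every builder is a deterministic function of the matrix. Negative NJ
branch lengths are clamped to zero with the deficit moved to the sister
branch. Balanced minimum evolution starts from the NJ topology and
hill-climbs nearest-neighbour interchanges on Pauplin's balanced tree
length L(T) = Σ_{i<j} d_ij·2^(1−p_ij) (p_ij = path length in edges),
accepting only strict decreases; final branch lengths are ordinary least
squares on the fixed topology, clamped at zero. Full SPR-based minimum
evolution search is out of scope.

The bootstrap resampling unit is the adjacency column: each replicate draws
the original number of columns with replacement and recomputes distances
with the multiplicities as weights. Supports are the percentage of
replicates containing each internal bipartition of the full-data tree. One
integer seed controls the run; replicate r draws from a substream keyed on
(seed, r), so results are independent of evaluation order, and a replicate
that leaves some genome without a scorable adjacency is rejected and
redrawn from substream (seed, r, attempt). Branch-length contrasts
(focal terminal branch minus the mean of a comparison set) use the
percentile 2.5/97.5 interval over replicates; terminal branches rather than
root-to-tip distances are contrasted because the trees are unrooted.

## Dollo parsimony

An adjacency is assumed to be gained exactly once (two independent
rearrangements essentially never create the same junction) and lost freely.
On a rooted tree the minimal scenario places the gain at the most recent
common ancestor of the leaves carrying the character and one loss at the
root of each maximal subtree inside that clade containing an observed
absence but no presence; missing states neither force nor block losses.
Steps = 1 gain + losses, so the reported totals include the obligatory
gains. The per-character scorer is validated against exhaustive enumeration
of every single-gain placement and loss subset on all rooted topologies
with up to six leaves; a vectorised scorer (identical by construction test)
handles matrices with thousands of characters. Scenario comparison scores
the lineage-specific characters — present in at least one ingroup species
and observedly absent from every outgroup — on both candidate topologies
after rooting on the outgroup clade; Dollo is direction-dependent, so
unrooted inputs must be rooted explicitly.

## Kishino–Hasegawa test

With paired per-character steps a_i, b_i and d_i = a_i − b_i, the statistic
is T = Σd_i with SE² = n/(n−1)·Σ(d_i − d̄)², z = T/SE, two-sided normal p
(z = 0, p = 1 when all d_i are equal). Because the normal approximation can
be unreliable when few characters discriminate, a seeded sign-permutation p
(random sign flips of the d_i, 10,000 draws by default, add-one corrected)
is always reported alongside; the two agree closely once hundreds of
characters carry signal, while at a handful of informative characters the
permutation p is the honest one.

## Fusion detection

One-to-one orthologs (single copy in both genomes of a comparison; post-WGD
genomes may optionally contribute families with two copies, counted once
per distinct chromosome pair) assign each gene a (chromosome-in-A,
chromosome-in-B) cell. Every populated pair is tested for sharing more
orthologs than expected under independence: Yates-corrected χ²
(N(|ad−bc|−N/2)²/((a+b)(c+d)(a+c)(b+d)), 1 df) or an explicit permutation
test that shuffles one genome's chromosome assignments (the analytic
expectation is exactly what shuffling converges to, which is why χ² is the
default). p-values are Bonferroni-corrected over the pairs actually tested,
and significance additionally requires observed > expected — enrichment,
not depletion. A derived chromosome significantly linked to ≥2 ancestral
chromosomes of which ≥2 are micro-chromosomes is called a
micro-chromosome fusion; ≥1 micro plus ≥1 macro is a macro+micro fusion
(precedence to the micro call when both patterns hold, since the question
is whether micro-chromosomes fused). One-to-one chromosome pairs are
mutually unique significant partners; this operationalises "one-to-one
chromosome orthology", which has no single standard definition.

## Simulator

The generator exists to produce data satisfying the analysis's premises
with known truth, not to model rearrangement biology realistically. The
ancestor has a configurable karyotype (the 14-taxon fixture: 6
macro-chromosomes of 740 genes and 8 micro-chromosomes of 70 genes; 1 kb
genes with 100 bp gaps, so marker-coverage fractions are well defined).
Along each branch, event counts per type are Poisson(rate × length) —
memoryless and additive — applied in random order: inversions reverse a
uniform segment (chromosome chosen proportional to gene count) and flip
strands; reciprocal translocations swap uniform terminal segments of two
chromosomes; fusions concatenate two chromosomes in random orientation;
fissions split at a uniform internal breakpoint; transpositions excise a
segment and reinsert it at a uniform position in random orientation. The
WGD duplicates every chromosome at a named internal node, then each gene
keeps both copies with probability p_retain = 0.2 (a realistic ohnolog
retention level) or loses a uniformly chosen copy; because resolution
happens once at the WGD node, the losses are shared by all descendants, as
for duplicates resolved before a radiation. Families equal ancestral gene
identity, so the emitted ortholog table is exact — the pipeline is tested
free of orthology-inference error, which real analyses delegate to
dedicated tools. Every event is logged with concrete operands and the log
replays from the ancestor to each tip exactly.

Fixture rates (inversion 1,400, translocation 45, transposition 140,
fusion/fission 1.5 per unit branch length on a tree with terminal branches
0.08–0.25) were chosen so pairwise distances span ≈0.1–0.7 — enough
divergence to be non-trivial, far from saturation — with the two "slow"
sister lineages on short terminal branches, mirroring the slowly evolving
holostean genomes the method was designed around. The fusion fixture keeps
one genome near-ancestral and applies three scripted micro-chromosome
fusions (plus intra-chromosomal inversions on both sides) to the other.

## What the simulations do and do not show

The simulator produces clean one-to-one families, complete genomes, and
i.i.d. rearrangements. Real data add orthology-inference error, assembly
gaps (handled only as missing adjacencies at scaffold boundaries),
lineage-specific post-WGD duplicate loss (the simulator resolves duplicates
once, at the WGD node, so its duplicated lineages share one resolution),
and rate heterogeneity along the genome. Passing the simulation suite
therefore demonstrates the correctness of the algorithms and the internal
consistency of the pipeline under its stated assumptions — not robustness
to annotation error, which must come from the marker filter's strictness.

## Numerical and design choices

- Distance ties (equal-size adjacency sets): average the two
  normalisations.
- NJ/UPGMA ties: lexicographic cluster labels; BME accepts the best strict
  improvement per sweep with a fixed edge ordering — all builders are
  deterministic.
- Bootstrap and permutation randomness: numpy Generator streams keyed on
  (seed, replicate[, attempt]); identical seeds give bit-identical results.
- Bonferroni denominators count the chromosome pairs actually tested
  (pairs skipped for zero marginals are logged, not counted).
- Degenerate inputs fail loudly: empty adjacency sets, characters with no
  present leaf, non-monophyletic outgroups, and zero-marginal tables are
  errors or logged skips, never silent zeros.

## Problem sizes in the validation suite

The default test run simulates twenty 14-taxon datasets of 5,000 genes
(plus rate ladders, fusion karyotypes and the exhaustive ≤6-leaf Dollo
enumeration) and completes in about a minute on one core; the acceptance
script runs one seed of each analysis in a few seconds. These sizes were
chosen to give stable pass/fail statistics (19/20- and 15/20-seed
thresholds) while keeping the suite fast enough to run on every change.
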