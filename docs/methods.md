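# Methods

This note documents the models and procedures implemented in
`barcodeaudit`, the parameter choices that matter, what the synthetic
generator does and does not emulate, and the numerical conventions used
throughout. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Sequence QC

Barcodes are protein-coding, so a sequence containing an in-frame stop
codon under the vertebrate mitochondrial code (TAA, TAG, AGA, AGG) is
treated as a pseudogene or artefact and excluded. The amplicon's reading
frame is generally unknown after primer trimming, so it is auto-detected
as the frame in {1, 2, 3} minimising the library-wide stop-codon total,
ties going to the lowest frame; a fixed frame can be forced. Codons
containing any non-ACGT symbol are untranslatable and can never register
as stops — deliberately conservative, since ambiguity should not cause
exclusion. The screen is idempotent.

Nucleotide composition is reported two ways: pooled over all unambiguous
sites of all records (primary) and as the mean of per-sequence GC
fractions (secondary). The two differ when sequence lengths or ambiguity
contents differ; both are emitted because published summaries rarely say
which convention they use.

## Distances

The only distance used is the *p*-distance with pairwise deletion: for a
pair of aligned sequences, sites where either symbol is not a plain
A/C/G/T are dropped *for that pair*, and the distance is
mismatches / comparable sites. A pair with zero comparable sites is
undefined (NaN) and excluded from every summary, never silently zeroed.
Because each pair may use a different site subset, this distance can
violate the triangle inequality; no algorithm in the package assumes
metricity.

Per species the package reports mean and maximum intraspecific distance
(over unordered conspecific pairs; undefined for singletons) and the
nearest-neighbour (NN) distance. NN is scored, by default, as the
*minimum* heterospecific specimen-pair distance involving the species —
this is the convention under which the barcoding-gap criterion
(max intra < NN) is meaningful point by point. A mean-linkage variant
(closest species by mean pairwise distance) is available via
`nn_semantics="mean"` because some published gap analyses describe their
NN as a mean; the minimum is the default because the gap logic of the
scatter plot depends on it. NN ties are broken lexicographically by
species name so reports are deterministic.

Distances are stored as fractions and converted to percent (×100,
half-up, two decimals) only in the report layer.

## Neighbour joining and bootstrap

The tree is classic Saitou–Nei agglomeration on the Q-criterion. Ties in
the Q matrix (common when many sequences are identical) are broken by the
lexicographically smallest pair of subtree representatives, where each
active node is represented by the smallest specimen id it contains; this
makes the topology independent of input order. Negative branch lengths
are kept internally and clamped to zero only for Newick display. The tree
is a clustering device over the distance matrix, not a phylogenetic
estimate.

Bootstrap support resamples alignment columns with replacement,
recomputes the distance matrix and NJ tree, and scores each internal
bipartition of the reference tree by the percentage of replicates
containing it. Replicate *r* draws from a dedicated RNG stream seeded by
(seed, *r*), so runs are bit-reproducible and replicates are independent
of how many are requested. Replicates in which any pair loses all
comparable sites are dropped and counted.

A species is *cohesive* when a single tree edge separates exactly its
specimens from all other leaves (unrooted monophyly); singletons are
cohesive by convention with undefined support.

## OTU delimitation

OTUs approximate the BIN system: stage 1 forms single-linkage connected
components over pairs at distance ≤ 2.2% (the published BIN seed
threshold; configurable). Stage 2 re-partitions any cluster whose
diameter exceeds twice the threshold using complete-linkage agglomeration
cut at the threshold. The BIN system's own cluster re-evaluation is
unpublished; this refinement stage is an explicit approximation and the
run metadata says so. Stage 1 is tested against a brute-force graph
connectivity oracle; the whole procedure is invariant to specimen order.

An OTU is concordant when all members carry one species label, discordant
otherwise, singleton when it has one member. The rank of conflict is
Species within one genus, Genus across genera, Family when an optional
genus→family table shows two families.

## Misidentification calls and review

A specimen is called misidentified iff (a) the majority label of its OTU
differs from its own field label, and (b) its mean distance to
majority-label specimens is smaller than its mean distance to own-label
specimens. When the specimen is its label's only representative, (a)
alone decides and the call is flagged low-confidence. Calls propose the
majority label as the barcode identification and are grouped by division;
the report's "x/y" denominator counts all barcoded individuals carrying
the field label in that division. The pipeline then relabels called
specimens and recomputes every label-dependent structure — the published
workflow order (curate first, then summarise).

Discordant OTUs are reviewed with three ordered rules: (1) *interim
names* — provisional labels (epithet "sp."/"sp"/"sp1"-style, possibly
with a trailing tag) are folded into the congeneric binomial when the OTU
contains exactly one; (2) *minority misidentification* — if afterwards
all but at most *k* records (default *k* = 2, matching the
one-or-two-record conflicts that morphological error produces) share one
species, the OTU is concordant with the minority flagged; (3) otherwise
it remains discordant (multi-species).

## Grades

Each species receives one grade, first matching rule wins, and every
grade carries a rule trace; inputs that fit no rule raise rather than
grade silently. With an external reference match table (an offline
stand-in for a live identification-engine query, so the package has no
network dependency): E when the match names a different species or the
species is para/polyphyletic; A when the match is to itself, the species
is cohesive and divergence ≤ 2%; C when the match is to itself but
divergence exceeds 2% (this reading of the "sub-optimal concordance"
criterion is an interpretation — the published wording is ambiguous — and
is documented here as such). Without a reference: B for ≥ 3 cohesive
specimens within 2%, C for ≥ 3 cohesive specimens beyond 2%, D for 1–2
specimens. The 2% criterion is evaluated on maximum pairwise *p*-distance
rather than tree-path (patristic) distance: at barcode scales the two are
nearly identical and the matrix is the package's primary structure.

A non-cohesive species whose specimens fall into ≥ 2 maximal pure
sub-clusters, each fully supported (bootstrap ≥ 95 by default; size-1
groups pass trivially), is split into provisional taxa "Species 1",
"Species 2" (by decreasing size) which then re-enter grading
independently. The differentiating substitution count reported is the
minimum pairwise mismatch count between groups — on clean two-lineage
data every cross pair gives the same count, and the minimum is the
conservative choice otherwise.

## Haplotype networks

Within a species, columns that are ambiguous in *any* conspecific record
are removed before collapsing (complete deletion), because per-pair
handling would make haplotype identity ill-defined; the retained column
indices are logged so mutation positions refer to the original
alignment. Haplotypes are named "H" + species initials + rank,
frequency-descending then first-seen.

The parsimony tree is found by exact branch-and-bound for ≤ 10
haplotypes, using Fitch counting with bitmask state sets over variable
columns and pruning on the monotone partial-tree score. Up to 8
haplotypes the co-optimal plateau is enumerated exhaustively, the
canonically smallest tree chosen and the co-optimal count reported; from
9 to 10 the bound also prunes ties (the score is still exactly optimal,
the tree is the first optimum in a deterministic insertion order). The
exact limit sits at 10 rather than higher because intraspecific data are
star-like and the number of equally parsimonious resolutions grows
explosively with haplotype count. Above 10, deterministic stepwise
addition plus first-improvement NNI hill climbing (capped sweeps) is
used and the score is an upper bound.

For the network, internal nodes receive Fitch up-pass/down-pass
sequences (down-pass prefers the parent state, otherwise the
lowest-ranked base — deterministic). Nodes with identical sequences are
merged, so internal nodes coinciding with sampled haplotypes disappear
into them and the remainder become frequency-0 median nodes, marked
distinctly in all outputs. Edges carry the Hamming distance between
adjacent sequences; every surviving edge weighs ≥ 1. On homoplasy-free
data the path length between sampled haplotypes equals their Hamming
distance (a tested invariant).

A haplotype is private to a division iff all its specimens with a known
division come from that division; specimens lacking a division are
excluded from privacy claims and reported. Single-division species are
flagged degenerate (every haplotype trivially private).

## Synthetic libraries

The generator draws a random ultrametric coalescent-shaped species tree,
scales it so the mean pairwise leaf divergence equals `inter_divergence`
(default 0.08 — the scale of congeneric COI distances in
chondrichthyans), and evolves ancestor sequences down it with Poisson
branch mutations. `sibling_pairs` override individual pairs with a
reduced divergence (e.g. 0.017, below the 2.2% OTU threshold, to emulate
recently diverged sibling skates). Specimens mutate from their species
ancestor with Poisson(`intra_theta` × L) substitutions; the default
`intra_theta` = 0.0015 per site makes the expected pairwise
intraspecific distance ≈ 2 × 0.0015 = 0.3%, the observed scale for these
libraries. Substitutions are Jukes–Cantor-like — uniform random target
base, positions drawn with replacement, back-mutation possible — because
the audit consumes *p*-distances only; realised divergences are therefore
checked against tolerance bands, not exact counts.

The default alignment length is 651: barcode amplicons are ~650 bp, and
a codon multiple keeps the injected reading frame unambiguous. All
"clean" sequences are kept stop-free by construction (stop codons arising
from random mutation are repaired back to the parent codon), so the QC
exclusion set provably equals the injected stop-codon set. Division-
private lineages apply a fixed set of extra substitutions to one
species × division combination. Artefact injection (label swaps between
congeners, interim names, stop codons, upstream sequencing failures) is
Bernoulli per specimen and recorded exactly once in the truth table.

Canned scenarios provide deterministic structures: a division-scale
misidentification batch (45 swapped labels among 146 carrying the field
label in one division, ≤ 300 specimens total, built directly so counts
are exact) and five per-species network shapes (8 haplotypes with one
division-private; a private haplotype exactly three mutations from the
rest; three haplotype groups partitioned by division sets; etc.), built
from hand-placed mutations rather than random draws so their qualitative
structure holds by construction.

What the generator does *not* emulate: rate heterogeneity among sites,
transition/transversion bias, indels and alignment error, contamination,
heteroplasmy, and geographically structured sampling effort. Passing
tests therefore demonstrate the audit logic is correct under the stated
statistical structure, not that real libraries meet that structure.

## Numerical conventions and problem sizes

Percent formatting is half-up to two decimals, applied only in report
tables; internal values keep full precision. Report "Average" rows are
unweighted means over species with defined values, per column. All
randomness flows from integer seeds; bootstrap replicates and the
simulator are bit-reproducible. The bundled analyses run at desk scale —
libraries of tens to a few hundred specimens, 1,000 bootstrap replicates
on two-species libraries, exact parsimony to 10 haplotypes — sizes chosen
so the full battery completes in minutes on one CPU while still
exercising every code path at the divergence scales described above.

## Known limitations

* The refined single-linkage stage 2 approximates an unpublished
  re-evaluation procedure; OTU boundaries for clusters spanning the
  threshold can differ from the reference system's.
* Misidentification calling requires the true species to dominate its
  OTU; when swapped records outnumber correct ones the majority vote
  inverts and the call set is wrong by construction (the degenerate case
  is detectable as reciprocal calls).
* Grades A/E are unreachable without a reference-match table; the
  pipeline then grades B/C/D only.
* NJ with negative branch lengths is reported as-is; only display is
  clamped.
* The NNI heuristic above 10 haplotypes gives an upper bound on the
  parsimony score, not a certificate.
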