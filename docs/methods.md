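# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `stuckenia-its`.

## The identification problem

The nuclear ribosomal ITS1–ITS2 spacer (~600–750 nt in pondweeds)
separates five *Stuckenia* taxa by a small, discrete set of characters:
a large difference block between *S. vaginata* and the *S. pectinata*
lineage (three indels of 1, 1 and 9 nt plus sixteen 1-nt and two 2-nt
substitution runs, corroborated by a CfoI restriction-site contrast —
one strict `GCGC` occurrence in *S. vaginata* vs. two in the lineage);
a 5+1 substitution-run dichotomy between *S. pectinata* types A and B;
a 2-nt state change at a diagnostic dinucleotide (nominal alignment
positions 102–103) separating *S. macrocarpa* from type B; and a single
T/C substitution (nominal position 524) separating *S. chakassiensis*
from type B.  Hybrids between type B and *S. macrocarpa* show IUPAC
additivity — the two-base union code at both dinucleotide positions.

## Alignment

`pairwise_global` is affine-gap global alignment (Gotoh, three-state DP)
with a deterministic traceback tie-break (diagonal > up > left,
evaluated everywhere in that order).  `progressive_msa` builds a UPGMA
guide tree on fractional-common-3-mer distances and merges profiles in
guide order with the same DP kernel; profile columns are scored as the
count-weighted average of residue-pair scores, with gap symbols scoring
zero against everything.  Guide-tree ties break on the sorted pair of
lexicographically smallest member labels, and the left profile in each
merge is the cluster with the smaller label, so the alignment is
independent of input order (rows are emitted in input order).

Default scores: match +2, mismatch −1, gap open −5, gap extend −1,
IUPAC codes matching when their base sets intersect.  No parameters are
inherited from any external aligner; these defaults were chosen so that
isolated short indels (the locus's 1/1/9-nt events) align as single
contiguous gap blocks, and they are configuration-exposed
(`ScoringScheme`).  An externally produced aligned FASTA can replace the
internal aligner (`RunConfig.aligned`), which is also the route for
analysing reference-database alignments.

Coordinates are 1-based inclusive alignment columns throughout;
`map_position`/`unmap_position` convert between a row's ungapped residue
numbering and columns.

## Distances

*p*-distance: mismatches over compared columns.  TN93: two transition
classes (A↔G with proportion P1, C↔T with P2) and transversions Q, with

d = −k1·ln(1 − P1/k1 − Q/2gR) − k2·ln(1 − P2/k2 − Q/2gY) − k3·ln(1 − Q/2gRgY),

k1 = 2gAgG/gR, k2 = 2gTgC/gY, k3 = 2(gRgY − gAgGgY/gR − gTgCgR/gY),

with base frequencies g estimated empirically from the compared columns
of each pair (pooled over both rows).  The pairwise-deletion default
excludes, per pair, any column holding a gap *or an ambiguity code*:
this preserves information across the 9-nt indel and prevents a hybrid's
K/M codes from inflating its distance to either parent.  Complete
deletion is available.  A transition class absent from the data
contributes its analytic limit of zero; saturated or
frequency-degenerate pairs yield a flagged NaN entry, never a silent
number.  The implementation is cross-checked in the test suite against
`ape::dist.dna(model="TN93")` on gap-free pairs (where ape's
pooled-frequency convention coincides with the per-pair one) and against
the Kimura-2-parameter closed form in the equal-frequency limit.

## Trees and bootstrap

Neighbor-joining with: Q-criterion ties resolved to the smallest pair in
label order (clusters keyed by their lexicographically smallest leaf,
making the topology independent of input row order); negative branch
estimates clamped to zero with the deficit moved to the sister branch;
and internal edges of ~zero length collapsed into polytomies, so
indistinguishable sequences yield a star-like tree rather than
arbitrarily resolved, spuriously "supported" splits.  NJ is exact on
additive matrices, which the test suite verifies against the path-length
matrices of random generating trees and against `skbio.tree.nj`.

Bootstrap resamples alignment columns with replacement; support of an
internal edge is the percentage of replicate NJ trees containing its
bipartition.  Per-pair column statistics (comparable-site indicator,
transition/transversion indicators, pooled base counts) are linear in
column weights, so all replicates reduce to one matrix product; replicate
TN93 entries that come out undefined (rare, extreme resamples) fall back
to that pair's p-distance so every replicate yields a tree.  Default
1000 replicates, seedable; display convention prints supports only when
strictly greater than 50 %.

This distance-based tree is a deliberate surrogate for full
maximum-likelihood topology search: the quantities this package is
accountable for are group memberships and split supports, which NJ on
TN93 distances reproduces at desk scale with a fully specifiable,
deterministic algorithm.

## Difference profiling

Two aligned rows are reduced to maximal runs: adjacent columns of the
same kind (substitution, insertion, deletion) merge into one event, so a
2-nt substitution is one event of length 2 and the 9-nt indel one event
of length 9.  Replaying the events onto one row reconstructs the other
exactly (round-trip property, tested).  Columns gapped in both rows are
neutral.

## The diagnostic key and classifier

Absolute alignment column numbers are an artifact of whichever master
alignment produced them and cannot be reproduced without the original
alignment run.  Every rule is therefore anchored by a 10-nt ungapped 5′
context string from a named reference haplotype (required to occur
exactly once there); the nominal positions (102, 103, 524) are retained
as metadata only.  The key file is human-editable YAML carrying the
rules, the reference sequences themselves, the motif (`GCGC`) and the
per-taxon strict-count expectations — so `analyze` is self-contained:
input samples are aligned together with the key's references.

Decision order: (1) vaginata/pectinata separator states, with the strict
motif count as corroboration — the larger difference set is primary
evidence because ambiguity codes can mask single diagnostic sites, and
any motif-count disagreement with the final call is recorded as a
conflict, never dropped; (2) type A/B separator states; (3) the
dinucleotide: B states lead to the position-524 rule (type B vs.
*S. chakassiensis*), macrocarpa states call *S. macrocarpa*, and the
exact additivity pattern at **both** positions calls a hybrid.
Additivity at only one position yields `unresolved` with a
"partial hybrid signal" conflict — a single ambiguous site is as likely
a sequencing artifact as a hybrid signature.  A gap at a diagnostic
position makes that rule uninformative but never blocks a call on the
remaining rules (so haplotypes carrying incidental deletions, which are
known at this locus, still classify).  Which of T/C at position 524
belongs to *S. chakassiensis* is a key-file parameter; the shipped
synthetic key assigns C to *S. chakassiensis* as an explicit arbitrary
choice, to be set from reference material when building a real-data key.

Groups mirror the locus's tree structure: I = *S. vaginata*, II = type
A, III–I = type B + *S. macrocarpa* + hybrids, III–II =
*S. chakassiensis*; unresolved samples are listed separately.

The ambiguity profile (share of non-ACGT residues, default flag
threshold 0.5 %) separates multiply-polymorphic samples (many
superimposed peaks; ~0.7 % in the simulated polymorphic sample) from
clean hybrids (exactly two diagnostic ambiguities, ~0.3 %).

Discordance reporting matches morphology labels to calls at the epithet
level, treating *Stuckenia* and *Potamogeton* binomials (and Latin
gender variants) as synonymous; "S. pectinata" is concordant with either
molecular type, and a hybrid call is concordant with either parent's
label.

## Synthetic data

The generator emulates exactly the difference structure above.  A
uniform-random 700-nt base sequence (the type-A haplotype) receives two
planted `GCGC` motifs (positions 150 and 400 by default), the diagnostic
states (G,C at 102–103; T at 524), and is scrubbed of accidental `GCGC`
occurrences.  Type B applies the 5+1 A/B substitution runs;
*S. macrocarpa* and *S. chakassiensis* derive from B by their single
diagnostic changes; *S. vaginata* applies the 16+2 substitution runs
(one single forced onto the third base of motif #2, mechanistically
producing the 2-vs-1 restriction-site contrast) plus three insertions of
1, 1 and 9 nt.  Constraints enforced by construction and verified per
attempt (bounded retry with fresh draws, deterministic per seed): no two
events overlap or sit adjacent (runs would merge), substitutions avoid
the A/B difference columns (the 16+2 runs are defined where A and B
agree; vaginata carries the type-A state at A/B columns — which is also
why, on the unrooted 5-haplotype tree, vaginata attaches on the type-A
side of the A/B split), indels stay ≥ 20 nt from any diagnostic position
or motif, every rule anchor is unique in the reference, and the strict
motif counts come out 2/2/2/2/1.

Hybrid samples are the position-wise IUPAC union of the type-B and
macrocarpa haplotypes (indel-identical parents).  Sample noise is
substitution-only at ≤ 5 % per site, never touching diagnostic or motif
positions, so the generating taxon remains well defined; "polymorphic"
samples additionally receive two-base ambiguity codes at ~1 % of sites
(at least five), emulating a consensus over superimposed peaks.  There
is no coalescent realism, indel noise, or chimera simulation — passing
tests demonstrate the pipeline's correctness on the locus's documented
difference structure, not robustness to arbitrary real-world artifacts.

The default simulated study is 28 samples (2 *S. vaginata*, 2 type A,
7 type B, 8 *S. macrocarpa*, 6 *S. chakassiensis*, 3 hybrids) whose
morphology labels recreate a realistic misidentification pattern
(morphology totals 7/7/9/5; six samples discordant with their molecular
call) plus one multiply-polymorphic type-B sample.

## Determinism and problem sizes

All randomness flows from explicit integer seeds
(`numpy.random.default_rng`).  Pipeline runs with identical
configuration and seed are bit-reproducible across every analysis
output; `run.log` carries wall-clock timings and is the sole exception.
The acceptance script uses a 20-seed battery of 11-sample panels for the
classification accuracy, the 28-sample study for group structure, and
200 bootstrap replicates (supports for the deep vaginata split are
saturated at far fewer; the pipeline default remains 1000).

## Known limitations

* The aligner is plain progressive alignment without iterative
  refinement; it is built for near-identical barcode haplotypes, not
  deep divergence.
* TN93 assumes site-independence and no rate heterogeneity (no +Γ);
  trees are unrooted and distance-based, not ML.
* The classifier is rule-based and returns no probabilistic assignment
  scores; samples outside the five-taxon panel come back `unresolved`
  rather than being placed.
* Restriction-site analysis is motif counting only (no fragment-length
  simulation).
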