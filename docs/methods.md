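# Methods

## The genetic setting

Both parents of the mapping population are doubled haploids, so they are
fully homozygous: every F2 marker is co-dominant with three distinguishable
classes (A = reference-parent homozygote, H, B = alternative-parent
homozygote) and every marker pair is in coupling phase.  That removes the
phase-inference step a heterozygous-parent cross would need and makes the
two-locus F2 likelihood exact and simple.

The monosomic addition lines (MALs) each carry the complete bunching-onion
genome plus one shallot chromosome.  At an interspecific SNP site (bunching
onion homozygous for the alternative allele, shallot DH homozygous for the
reference allele), the MAL carrying the shallot chromosome of the unigene is
heterozygous and the other seven are alternative-homozygous.  The anchoring
stage is exactly this signature read off per site, then aggregated per
unigene.

## Anchoring rules

Sites enter anchoring only when all eight MAL depths are ≥ `mal_min_depth`
(default 4) and the parental pattern holds; dropped sites are counted under
one reason each, depth checked first.  A retained site is *clean(c)* when
MAL c is the unique heterozygote (and no MAL call is missing), otherwise
*ambiguous* — zero heterozygotes (the gene was not expressed from the added
chromosome) or several (partial homology between the shallot and
bunching-onion copies).  Per unigene:

- one clean site → `ONE_SNP`;
- ≥ 2 sites, all clean and agreeing → `MULTI_CONSISTENT`;
- a mix of ambiguous and agreeing clean sites → `REPRESENTATIVE`, the
  representative being the clean site with the highest minimum MAL depth
  (ties: smallest position) — depth is the natural reliability proxy here;
- no clean site, or clean sites naming different chromosomes →
  `UNASSIGNED`.  The conflicting-clean case is deliberately left
  unassigned: the data pattern has no textbook interpretation and a
  majority vote would manufacture evidence.

## S/O/R marker consolidation

F2 sites are retained when (a) the parents show the expected homozygous
pattern, (b) every line has depth ≥ `f2_min_depth` (default 2), and
(c) at least one line is heterozygous (co-dominance).  Sites on one unigene
are perfectly linked, so their 96-line patterns should be identical;
disagreement is genotyping error.  Consolidation:

- single retained site → class **O**;
- some pattern shared by ≥ 2 sites → class **S** with that pattern
  (support = multiplicity).  A third, discordant site does not disqualify
  the unigene — the shared pair is the evidence; a `strict_solid` flag
  demands all-identical instead.  When two patterns are each shared, the
  higher multiplicity wins, then the pattern with more heterozygous calls
  (the dominant error destroys H calls, so the H-richer pattern is the
  likelier truth), then the earliest supporting position;
- all patterns distinct → class **R**, the per-line modal call.  A modal
  tie that includes H resolves to H for the same reason; an A-vs-B tie
  carries no information and is emitted as missing with the line flagged.
  Missing entries can enter marker vectors *only* through this tie.

## Two-locus likelihood and r estimation

With gamete haplotype probabilities (1−r)/2 (parental) and r/2
(recombinant), the joint 3×3 class table of an F2 line is the convolution of
two independent gametes; e.g. P(A,A) = (1−r)²/4 and
P(H,H) = ((1−r)²+r²)/2.  Every class determines its number of recombinant
gametes (0, 1 or 2) except the double heterozygote, which mixes
parental×parental with recombinant×recombinant.  The MLE is computed by EM
on the expected recombinant-gamete count, with the double-heterozygote
posterior weight r²/(r²+(1−r)²); the update is clipped to [0, 0.5]
(repulsion-leaning tables have their maximum at the boundary).  Convergence
tolerance 1e-12, initial value 0.25.  The estimator is vectorized over all
marker pairs at once (nine indicator-matrix products give all two-locus
count tables).  Tests and the acceptance checks compare it against an
independent likelihood grid scan (step 1e-4); agreement is required to
|Δr̂| ≤ 1e-3.  Lines with a missing call in either marker are skipped
pairwise; pairs with < 10 informative lines are flagged low-confidence.

LOD is the linkage LOD, log10 L(r̂) − log10 L(0.5) (not an independence
LOD); the grouping threshold (default 5) is configurable.

## Grouping, ordering, distances

Grouping is the transitive closure of the LOD ≥ threshold graph (connected
components).  Ordering minimizes the sum of adjacent recombination fractions
(SARF): a greedy chain grown from the tightest pair, refined by 2-opt
segment reversals until no reversal improves (a reversal changes only its
two boundary adjacencies, so each candidate move is O(1)).  The objective is
locally optimal under 2-opt, not globally — adequate here because marker
density keeps adjacent r small and informative.  Orientation of a group is
arbitrary; it is canonicalized by putting the terminal marker with the
lexicographically smaller identifier first, so outputs are reproducible.

Distances come from the Kosambi function d = 25·ln((1+2r)/(1−2r)) cM
(inverse r = tanh(2d/100)/2), with Haldane d = −50·ln(1−2r) as an
alternative.  An adjacent r̂ within 1e-6 of 0.5 — possible after ordering
noise — would map to an unbounded distance; it is capped at the function's
value at r = 0.49 and the interval flagged, rather than propagating an
infinity.

Groups inherit chromosome labels by majority vote over their MAL-anchored
members; disagreeing members are counted as conflicts but kept.  Map
comparison reports, per group, whether shared markers co-group in the other
map and the Spearman rank correlation of their positions, with the sign
chosen to maximize |ρ| (orientation is meaningless) and reported.

## Genotype blocks

Within an ordered group, maximal runs of markers with identical line
vectors form blocks — between adjacent blocks at least one line recombined.
O/R markers are matched against *all* blocks genome-wide (the restriction
to the anchored chromosome is available as an optimization flag but not the
default, since the intended semantics is "most similar block anywhere");
allocation requires the minimum mismatch count (lines where both calls are
non-missing and differ) to be unique and ≤ `max_block_mismatch` (default
10).  Ties are left unallocated rather than broken arbitrarily.  A marker
with > 20% missing lines is never allocated — with missing treated as
mismatch-neutral, a mostly-missing vector would match almost anything.

## The synthetic generator

`maplink.simulate` emulates, at the genotype-call level (no reads):

- **Genome**: 8 chromosomes splitting a configurable total length (default
  936.6 cM, equal lengths) with unigene loci placed uniformly; per-unigene
  SNP-site counts default to 1 with probability 0.395, else 2 + Poisson(2.5)
  (≈ 4.5 sites per multi-SNP unigene).
- **Meiosis**: each line is the union of two independent gametes; a gamete
  is a Markov chain along the ordered loci with interval crossover
  probability given by the *inverse of the selected mapping function*
  applied to the cM gap, and no interference across intervals.  Using the
  same function for simulation and estimation makes parameter recovery an
  exact expectation — the generator validates the estimator, it does not
  claim Kosambi-level interference realism.
- **Depth**: each SNP site draws an expression level
  λ ~ Gamma(shape = `depth_dispersion`, mean = `mean_depth`) shared by all
  samples, and each sample's depth is Poisson(λ) — marginally
  negative-binomial.  The hierarchy matters: expression varies between
  genes far more than between siblings of one cross, and the
  "all lines ≥ 2 reads" filter then selects well-expressed sites, as it
  does in real data.  Depth 0 always yields a missing call.
- **Heterozygote dropout**: at a true heterozygote, reference reads are
  Binomial(depth, 1/2) and H is called only if both alleles are seen
  (`min_alt_reads` = 1), so the dropout probability is 2·(1/2)^depth —
  0.5 at depth 2, negligible at depth ≥ 15.  Sites within a unigene get
  independent depth and allele draws, which is what produces discordant
  patterns and hence the S/O/R split.  An optional depth-independent
  dropout floor models allele-biased expression (default 0).
- **MAL noise**: per site, the carrier call collapses to homozygous with
  probability ε (`mal_dropout_rate`, default 0.02) and one random
  non-carrier becomes heterozygous with probability δ
  (`mal_spurious_het_rate`, default 0.02) — the two mechanisms the
  anchoring ambiguity rules exist for.

All generators are pure functions of (parameters, seed).

What the generator does *not* model: crossover interference, segregation
distortion, mapping/alignment artifacts (paralog collapse, reference bias),
linked error correlation between sites of one unigene, and sample quality
variation.  Passing recovery tests therefore demonstrates correctness of
the inference machinery under the stated model, not robustness to every
pathology of real RNA-seq genotyping.

## Problem sizes and what the checks show

The default synthetic study uses 800 unigenes (~100 per chromosome), 96 F2
lines and mean depth 20, giving ~430 solid markers — about 55 per
chromosome at ~2 cM spacing.  This is deliberately smaller than the
published study (1,435 solid markers from 5,339 unigenes) while keeping the
per-chromosome marker density in the regime where LOD-5 grouping and SARF
ordering are well-posed.  At 96 lines a chance association between unlinked
regions crosses LOD 5 in roughly one replicate in twenty, merging two
groups; group-count recovery is therefore assessed over 20 replicates
(expected ≥ 95% with exactly 8 groups) rather than on a single draw, and
the acceptance script reports it that way.  Recovered map length is
compared against the truth *span* of the mapped markers (terminal-to-
terminal), not the full chromosome length, since markers cannot map
telomeric segments they do not cover.

## Known limitations

- Ordering is heuristic (greedy + 2-opt on SARF); no multipoint likelihood.
- The linkage LOD differs from JoinMap's independence-test LOD, so group
  boundaries can differ from JoinMap's at the same nominal threshold.
- Multi-allelic VCF records are rejected (or optionally dropped), never
  decomposed.
- The VCF reader takes calls at face value; no genotype-quality modeling
  beyond the depth filters.
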