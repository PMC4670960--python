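# Methods

This note documents the models, conventions and design choices behind
`mrhet`, in the order the pipeline runs them.

## Input model and conventions

A patient is a set of labeled regions: tumor regions (optionally including
one metastasis) and at most one matched normal. Variants are 1-based
VCF-style records (anchored alleles: an insertion's alt begins with the ref
base); copy-number segments are 0-based half-open BED-style intervals.
Readers convert at the boundary, merge overlapping same-state CNV intervals
per region, collapse duplicate variant records, and split multi-allelic ALT
fields; everything downstream consumes validated domain objects only.
Consequence annotation is mapped from ANNOVAR-style tokens through a
documented dialect table; unknown tokens become `other` with a log message
rather than aborting, because token dialects drift across annotators.

## Heterogeneity statistics

All mutation heterogeneity statistics are **gene-level**: a gene is present
in a region when at least one variant of the selected consequence classes
(default: the non-silent set — nonsynonymous, stop-gain, splice-site,
frameshift and non-frameshift indels) was called there. Counting genes
rather than variants matches how multi-region studies report shared
mutation fractions; a variant-level character matrix remains available for
phylogenetics. The matched normal is excluded from every heterogeneity
statistic and serves only to root the tree.

Trunk = present in all regions; private = present in exactly one; branch =
the rest. With a single region every gene is trivially trunk (rate 0,
logged as degenerate); an empty matrix yields the all-zero report.
Heterogeneity rate = (total − trunk)/total. Reported percentages are
rounded half away from zero to integers, which is how the published
contingencies they are compared against were rounded (e.g. 23/193 → 12%).

Venn cells are exact per-subset tallies (up to 6 regions; 2^k cells), and
the mutation spectrum strand-collapses every SNV to its
pyrimidine-reference representation, so it is invariant under complementing
the inputs — a property test enforces this.

## Copy-number commonality

"Amplified in all regions" is only well-posed on a common grid, so all
regions' breakpoints are unioned per chromosome and each resulting atomic
interval gets one state per region (amplification overlapping deletion
within one region is rejected as a caller inconsistency, with the locus
named). Commonality counts atoms, not base pairs: published analyses count
"segments/loci", and atom counting is invariant to how finely an upstream
segmenter happened to split an event. `strict` mode requires the state in
every region; `lenient` drops regions with zero events of that state from
the denominator — provided because studies sometimes report "common"
deletions shared by all regions that have any deletion at all. Strict is
the default; lenient counts are never smaller (tested).

## Phylogeny

Characters are binary gene presences; the normal is an all-absent row.
Distances: mismatch fraction *p* (`p_distance`), or the
Cavender–Farris–Neyman correction `d = −½·ln(1 − 2p)` (`cfn`, default) —
the two-state analogue of corrected nucleotide distances, adopted because
no published two-state reading of a "generalized Kimura" distance exists
for presence/absence data. For p ≥ 0.5 the correction is undefined; the
distance is capped at p = 0.49 (d ≈ 1.956) and logged. A known consequence:
a mutation-free outgroup is saturated against regions carrying more than
half of all sites, so its distances compress uniformly to the cap —
harmless for rooting, but corrected distances on such data are not
additive, which is why `p_distance` (exactly additive on noise-free
simulated data) is offered alongside.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion, with ties broken by the smallest index pair in the current
ordering (making output deterministic on degenerate inputs), negative limb
lengths clamped to zero, and the final three nodes resolved by the
three-point formulas. NJ is exact on additive matrices; a property test
verifies topology and branch lengths on random trees up to 8 taxa.

Maximum likelihood uses the symmetric two-state Markov model with equal
stationary frequencies: P(different | t) = (1 − e^(−2t))/2. Site
likelihoods come from Felsenstein pruning (verified against exhaustive
enumeration over internal-state assignments on trees up to 6 leaves).
Branch lengths are optimized coordinate-wise with bounded scalar
minimization (tolerance 1e−6), sweeping until the log-likelihood improves
by less than 1e−8; the default search optimizes lengths on the NJ topology,
and `nni` additionally accepts nearest-neighbor interchanges while they
improve the likelihood. NNI candidates are evaluated from fresh uniform
branch lengths (0.5): when the incumbent's lengths have saturated at the
bound, the likelihood surface is locally flat and a warm start cannot
escape it. Optimization operates on the unrooted tree (the model is
reversible).

Bootstrap: characters are resampled with replacement; each replicate is
rebuilt by the same distance + NJ (+ optional ML) path; the support of an
internal edge is the percentage of replicates containing the same
bipartition. Replicate *r* draws from the substream keyed by (seed, *r*),
so results depend only on the seed, not on execution order. Supports are
stored keyed by bipartition, so rerooting (placing the root at the midpoint
of the normal's terminal edge) preserves them exactly.

## miRNA seed sites

Site classes follow canonical seed matching against miRNA positions 2–8:
8mer (reverse complement of nt 2–8 followed by A), 7mer-m8 (reverse
complement of nt 2–8), 7mer-A1 (reverse complement of nt 2–7 followed by
A). Each UTR position yields at most one site per miRNA, classified at its
strongest type; the 7mer patterns contained inside an 8mer are the same
physical site and are not re-reported. Mutation impact is called by
rescanning the mutated sequence and diffing site lists matched by (miRNA,
type, start), with starts downstream of an indel shifted back by the net
length change so unaffected sites are not spuriously flagged. Positions are
0-based on the supplied UTR; genome-to-UTR mapping is the caller's
responsibility. Thermodynamic scoring, conservation filtering and
3'-compensatory sites are out of scope — this is a deterministic,
testable seed-match proxy for heavier target predictors, and a precomputed
site list can be supplied instead.

## Clonal simulator

The generator emulates the structure of a multi-region exome study of a
single tumor. A clone tree grows by random recursive bifurcation until one
leaf clone exists per sampled region (one dominant clone per region;
region-level presence/absence cannot resolve admixture, so none is
simulated). Mutated genes are placed on edges: a fixed count `n_trunk` on
the root edge, Poisson(`mean_branch`) per internal edge,
Poisson(`mean_private`) per terminal edge; a region observes the union of
genes on its clone's root path. Defaults (4 regions, n_trunk = 20,
mean_branch = 18, mean_private = 25) give ≈155 mutated genes of which
≈13% are trunk and the heterogeneity rate is ≈0.87 — the regime multi-
region tumor studies report (~10–13% trunk, ~90% heterogeneity). The
optional metastasis clone attaches as a child of a uniformly chosen
non-root clone; when that clone is internal the generating region tree
contains a true polytomy, so a fully resolved inferred tree necessarily
carries one extra split — exact topology recovery is therefore a property
of the bifurcating scenario.

Simulated substitutions draw from a transition-heavy spectrum
(C>T/G>A 40%, T>C/A>G 22%, remaining four classes ~10% each, strand chosen
uniformly), consequences from a non-silent-dominated token mix, and CNV
segments (0.2–2 Mb) are placed without overlap: `n_cnv_shared` on the root
(all regions), `n_cnv_private` per region. Observation noise applies
per-entry dropout and false-positive rates to the presence table after the
clean assignment; both default to 0 so that the generator's identity
property (pipeline output equals generating truth exactly) holds by
construction and any deviation is a pipeline bug.

What the simulator does *not* emulate — allele frequencies, read-level
error, admixed regions, selection, realistic gene coordinates — bounds what
passing recovery tests show: they validate the statistics and tree
reconstruction on cleanly observed regional presence data, not robustness
to upstream calling artifacts beyond the simple dropout/false-positive
model.

## Reporting and reproducibility

Every pipeline output carries the tool version, a hash of the
analysis-defining config fields (the output directory is excluded, so
reruns into different directories are bit-identical), and the seed. All
randomness (simulator, bootstrap) flows from explicit integer seeds.

`scripts/acceptance.py` reconstructs worked examples from published
marginal counts using deterministic fixture builders
(`matrix_from_category_counts`, `atoms_from_common_counts`) and runs them
through the same classifiers as real data; stochastic checks use 10
simulated patients and a 1000-replicate bootstrap on the compatible-
characters fixture (5 taxa × 300 sites), sizes chosen so the whole script
completes in seconds on one CPU while leaving the recovery properties
sharply testable.

## Known limitations

- The CFN correction saturates for p ≥ 0.5 (see above); distance capping
  keeps the pipeline total but compresses long branches.
- Gene-level presence hides multiple hits in the same gene; variant-level
  characters recover them for phylogenetics only.
- Trunk/branch/private classification is presence-based and inherits any
  upstream calling errors; the dropout experiments in the test suite give
  a sense of sensitivity (≥90% category accuracy at 5% dropout in the
  default scenario).
- The seed-site scanner deliberately ignores binding energetics and
  conservation; its calls are necessary, not sufficient, evidence of
  regulatory disruption.
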