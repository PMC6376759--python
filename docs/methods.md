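# Methods

This note records the models behind each stage, the parameters that matter,
and the design decisions taken where more than one reasonable construction
existed. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sequence handling

All sequences live on one canonical RNA alphabet {A, C, G, U, N}; DNA input
is rewritten T→U on read. Coordinates are 1-based and inclusive on both
ends, matching how precursor windows are printed in the packaged tables.
The three packaged tables (per-species mature census; 20 novel precursor
windows with reported minimum free energies; unique mature clusters with
their target sites, expectation scores and inhibition modes) are stored as
tab-separated text exactly as printed and verified against a row-count and
checksum manifest at load time. Two printed rows are internally
inconsistent — one window is 173 nt against the stated 170-nt cap, and one
mature sequence contradicts its own cluster assignment — and are stored as
printed with explicit flags rather than silently corrected.

## Homology scan and window extraction

Candidate loci are found by an exact sliding-window Hamming comparison of
the mature query against both strands (`max_mismatches` defaults to 0, the
setting under which the family was annotated; raising it generalizes the
scan to cross-species search). All overlapping hits are reported — tandem
MIR loci exist — and minus-strand hits keep forward-strand coordinates.
Windows are cut with flanks measured in the mature's own orientation,
defaulting to 75/75 so that flanks plus a 20-nt mature meet the 170-nt
precursor cap; clipping at subject boundaries adjusts the mature offset.
The tRNA/rRNA exclusion of the original workflow is an interface, not a
re-implementation: `screen_candidate` applies an ordered list of
predicates (built-ins: single-nucleotide content > 80%; a ≤ 6-nt motif
tandemly covering > 60% of the window) and external scanners attach as
additional callables. A predicate that raises is reported but keeps the
window, since screening should err toward retention.

## Folding engine

`fold_structure` maximizes the number of canonical pairs (A–U, G–C, G–U)
subject to a minimum hairpin loop of 3 nt, breaking ties among
maximum-pair structures toward the most stacked pairs. Both objectives are
solved exactly in one dynamic program by scoring pairs at a large fixed
weight (1024) and stacks at 1, so the reported pair count always equals
the plain Nussinov maximum (property-tested against an independent DP).
The kernel is numba-compiled with a pure-Python fallback.

The energy estimate is an additive surrogate: −2.0 kcal/mol per stacked
pair of pairs, −1.0 per isolated pair, +0.1 per unpaired position enclosed
by at least one pair. It ranks hairpins sensibly and gives the validator
an energy axis, but it is not a thermodynamic (Turner-parameter) energy;
reproducing the packaged tables' printed MFE values is explicitly out of
scope, and an external thermodynamic folder (e.g. ViennaRNA) can be
substituted wherever a structure is consumed.

## Stem-loop validation

A candidate passes when all four criteria hold:

* **pairing** — at least 18 of the mature's positions are base-paired
  (`min_mature_paired`, default 18 of a 20-nt mature);
* **single stem** — those pairs sit in one unbranched stem. Mature pairs
  are grouped into ladders (consecutive paired mature positions whose
  partners lie on the same side, nest properly, and have nothing else
  paired in the bulges between them); the criterion tolerates as many
  stray positions outside the dominant ladder as the pairing criterion
  already forgives (mature length − 18, i.e. 2), because exact pair
  maximization routinely parks one or two co-optimal pairs elsewhere;
* **central loop** — beyond the loop-side end of that dominant stem lies a
  hairpin loop entirely outside the mature span. Incidental pairs folding
  *inside* the terminal loop are tolerated; the loop they enclose still
  counts;
* **energy** — surrogate energy ≤ `energy_cutoff` (default −15 on the
  surrogate scale; the original analysis printed per-precursor MFEs but no
  cutoff, so this is the package's own, deliberately permissive, default —
  a bare 18-pair stem scores well below it).

Because a fixed symmetric window is a *search* window rather than a
precursor, validation folds proposed sub-windows — the mature plus a
growing 3′ extension, then a growing 5′ extension (4-nt steps, minimum
16 nt), finally the full window — and accepts the first candidate that
passes (`best_precursor_report`). This mirrors how precursor-proposal
tools bound the hairpin before structure checking, and it makes recovery
of a planted perfect hairpin a structural property rather than a race
against background base pairing; without it, pair maximization over 150 nt
of random flank sporadically absorbs the mature into globally
higher-pairing but biologically meaningless structures.

## Unique-sequence clustering and identity statistics

Deduplication is greedy complete-linkage over equal-length sequences:
unique sequences are processed by descending abundance (ties
lexicographic) and join the first cluster in which they are within
`bracket_tolerance` substitutions of *every* member (default 0 = exact
identity; 1 reproduces bracketed cluster representatives of the
`[C/U]` kind). Complete linkage stops chains of near-neighbours from
bridging distinct clusters. Clusters are numbered by descending size and
represented by their most frequent member.

Pairwise identity uses a pairwise-deletion denominator (columns where both
members are non-gap), consistent with the distance convention below. The
two-sample Kolmogorov–Smirnov statistic is the exact ECDF sup-difference;
its p-value comes from the asymptotic Kolmogorov distribution evaluated at
√(n·m/(n+m))·D. The original analysis ran its KS test inside an alignment
editor without stating the two samples; the reproducible comparison
defined here is mature-family identities vs precursor-family identities,
alongside the fraction-above-threshold summaries (≥ 90% for matures,
≥ 55% for precursors) that the conservation claim is phrased in.

## Target scoring

The expectation score is a penalty-minimal antiparallel global alignment
(affine-gap Gotoh DP): Watson–Crick 0, G:U wobble 0.5 (never
seed-multiplied), mismatch 1.0 with ×1.5 inside the seed (miRNA positions
2–7), gap open 2.0 / extend 0.5, scored over miRNA positions 1–20 only —
a 22-nt mature's two 3′ positions pair for free. The published source of
these tables prints scores but no formula; this weight set is the
psRNATarget/miRU convention and is pinned by the requirement that all 16
printed rows reproduce exactly, which the acceptance suite verifies.
Ties break toward fewer gaps. The maximum reported E is 5.

Inhibition mode: Translation iff the duplex centre is disrupted — a
mismatch or mature-side bulge at positions 9–11, or a site-side bulge
strictly inside 9–11; wobbles and Watson–Crick pairs there leave the site
cleavable. Transcript scanning scores windows of length len−2 … len+2 at
every start, keeps each start's best alignment (ties to the fewer-bulge
duplex), and reports non-overlapping hits with E ≤ 5 ordered by (E,
position). The "UPE" accessibility column of the original tables needs a
partition-function model and is replaced by an explicitly labelled proxy
(paired fraction of the site ± 17 nt under the internal fold, scaled);
it is reported, never filtered on, and never compared to printed values.

## Phylogenetics

Alignment is center-star progressive: the center minimizes summed pairwise
edit distance (unit costs); pairwise alignments against the center merge
under "once a gap, always a gap". Distances are p-distances with pairwise
deletion; a pair with no shared non-gap column is an error, not a silent
zero. Trees come from Saitou–Nei neighbor joining with the standard Q
criterion, ties broken toward the lowest taxon-index pair; negative branch
estimates are clamped to zero with the deficit moved to the sister branch,
preserving the joined pair's path length. Bootstrap resamples alignment
columns with replacement (seeded generator; default 1000 replicates, the
published setting) and reports per-edge bipartition percentages. NJ is the
implemented estimator throughout; the original study's likelihood trees
(GTR+G+I) are out of scope, and the arm-separation claim — 5′-arm unique
sequences vs 3′-arm unique sequences across one internal edge — is checked
on the NJ tree, where it holds with high bootstrap support.

## Synthetic data

The generator writes the conditions the analysis assumes, with a manifest
for every planted feature:

* **genomes** — uniform background (25% each base), default 8000 nt
  carrying 19 hairpin implants (matching the count of novel precursors
  sharing the canonical mature) and 19 decoys, each placed ≥ 30 nt apart
  on a random strand. An implant is mature + loop (8 nt, random) +
  reverse-complement arm, the arm mutated per-site at `arm_mutation_rate`
  (default 0: the annotation-recall condition). A decoy is a
  dinucleotide-preserving shuffle (Eulerian-walk resampling) of such a
  unit — same composition and dinucleotide statistics, no planted hairpin,
  and almost never a surviving exact mature, so decoys probe the whole
  discovery chain rather than only the folder.
* **families** — a root sequence diverged along a known Newick tree; each
  branch substitutes each site with probability 1 − exp(−rate·length),
  jumping uniformly to another base. This chain composes exactly (the
  two-leaf mismatch probability is (3/4)(1 − Π(1 − 4q/3)) over the path),
  which the simulation tests use as their oracle.
* **transcripts** — sites built by editing the perfect complement per
  penalty recipes (named mismatch/wobble/bulge edits at named miRNA
  positions) with the intended E recorded, so scan results are checkable
  to the digit.

What the generator does **not** emulate: real base composition, repeats,
splicing, multi-locus gene families with divergent paralogs, or
expression. Passing the recall/rejection tests therefore demonstrates the
pipeline's correctness on its own model of the data, not discovery
performance on real genomes.

## Numerical and degenerate-input choices

Penalties are exact binary fractions, so score comparisons use direct
equality with a 1e-9 guard. The fold DP's pair weight (1024) exceeds any
possible stack count, making the (pairs, stacks) objective exactly
lexicographic in one integer. Windows shorter than twice the minimum loop
refuse to fold; empty FASTA subjects produce empty reports and a warning,
not an error; scanning with N in the query is rejected while N in the
subject simply never matches. All stochastic stages take explicit seeds
and are bit-reproducible; two pipeline runs with the same config and seed
write byte-identical artifacts.

## Problem sizes

The test suite exercises the recall/rejection experiment at seeds 1–100
(1900 implants, 1900 decoys), the alignment oracle at 500 random pairs,
the fold oracle at 200 random 40-nt sequences, and NJ recovery at random
additive trees of up to 8 taxa; `scripts/acceptance.py` repeats the
recall/rejection experiment at 30 derived seeds (570 implants/decoys) and
everything else at full size. These sizes were chosen to keep the complete
check runnable on a laptop-class single core in minutes while leaving the
statistical assertions comfortably powered.

## Known limitations

* The folding engine is combinatorial, not thermodynamic; its energies are
  surrogates and its structures can differ from minimum-free-energy
  structures, which is why validation proposes trimmed candidates instead
  of trusting one global fold of a 170-nt window.
* The expectation-score scheme is pinned by 16 printed rows; other weight
  sets consistent with those rows (e.g. end-free terminal gaps instead of
  a truncated scoring window for 22-nt matures) cannot be distinguished
  from the published values alone.
* Complete-linkage deduplication depends on processing order for
  tolerance > 0; order is fixed (abundance, then lexicographic) so results
  are deterministic, but other orders could merge borderline clusters
  differently.
* The center-star aligner is adequate for short, highly similar families;
  it is not a general progressive aligner and makes no claim of optimal
  multiple alignment.
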