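# mirfam

Annotation and co-evolution analysis of a conserved plant miRNA family
(miR394 and its *F-box*/*LCR* targets), packaged as a tested, reusable
Python library.

Plant miR394 is a ~20-nt small RNA that silences *LEAF CURLING
RESPONSIVENESS*, an F-box gene central to shoot stem-cell regulation.
Annotating such a family across species means answering four questions,
each covered by a module here:

1. **Where are the precursor loci?** (`homology_scan`, `hairpin`) — scan
   genomes on both strands for the mature sequence, cut a candidate window
   (≤ 170 nt), and validate the stem-loop: ≥ 18 of the mature's positions
   base-paired in one unbranched stem, followed by a central loop, with
   acceptable folding energy.
2. **Which mature variants exist?** (`mature_clustering`) — collapse
   cross-species matures into unique clusters (UmiR sets) and quantify
   conservation via pairwise-identity distributions and a two-sample
   Kolmogorov–Smirnov test.
3. **What do they target?** (`target_scoring`) — score miRNA:site duplexes
   with a penalty-based *expectation score* and call the silencing mode.
4. **How did family and targets co-evolve?** (`phylo`) — center-star
   alignment, p-distance with pairwise deletion, Saitou–Nei neighbor
   joining, column-resampling bootstrap, Newick output.

A `synthetic_data` module generates ground-truthed genomes, transcripts and
diverged families so every stage is testable offline, and `pipeline` /
the `mirfam` CLI run the whole workflow from one TOML config.

## The expectation score

A candidate site is aligned antiparallel to the miRNA (5′→3′ against
3′→5′, affine-gap global alignment) and penalized per miRNA position *i*:

| event | penalty |
|---|---|
| Watson–Crick pair | 0 |
| G:U wobble (either orientation) | 0.5 |
| mismatch | 1.0 × 1.5 if *i* ∈ seed (positions 2–7) |
| gap open / extend | 2.0 / 0.5 |

Only miRNA positions 1–20 (5′-anchored) are scored; E = Σ penalties, and
sites with E > 5 are discarded. A mismatch or bulge at the duplex centre
(positions 9–11) calls **Translation**, otherwise **Cleavage**. With this
scheme every one of the 16 packaged unique-target-site rows reproduces its
printed E-value and inhibition mode exactly (see the worked example).

## Worked example

```bash
python examples/01_reproduce_target_scores.py
```

prints one row per packaged unique target site:

```
site computed E printed E  mode         printed mode
  1a          1         1  Cleavage     Cleavage
  1d          3         3  Translation  Translation
  1e          0         0  Cleavage     Cleavage
  1g        2.5       2.5  Cleavage     Cleavage
  ...
16/16 sites reproduce the printed score and mode exactly.
```

E = 0 (site 1e) is the perfect complement of the most widespread unique
mature sequence; site 1a's single non-seed mismatch costs 1.0; site 1g
combines a seed mismatch (1.5) with a non-seed mismatch (1.0); site 1d's
central bulge flips the call to translational repression.

The other examples discover implanted precursors in a synthetic genome
(`02`, recovering 6/6 implants with a 20/20-paired stem at −39.4 surrogate
kcal/mol), contrast mature-like vs precursor-like conservation (`03`:
fraction of pairs ≥ 90% identity 0.321 vs 0.000, KS D = 1.0), and build
the bootstrapped NJ tree of the eight unique matures (`04`), whose
5′-arm representatives split from the 3′-arm representatives across an
internal edge with 92% support — the family's reported arm-wise clustering.

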