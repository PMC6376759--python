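"""Collapse mature sequences into unique clusters and contrast conservation.

The packaged novel-precursor table carries 20 putative mature sequences;
deduplication collapses them to their unique variants.  The second half
simulates a mature-like (slowly evolving) and a precursor-like (fast)
family along the same tree and compares their pairwise-identity
distributions: the fraction of pairs at >= 90% identity and a two-sample
Kolmogorov-Smirnov test, the package's reproducible version of the
mature-vs-precursor conservation contrast.
"""

import numpy as np

from mirfam import dedupe_unique, evolve_family, ks_two_sample, load_fixtures, pairwise_identity_matrix
from mirfam.seqio import MatureMiRNA

tables = load_fixtures()
matures = [MatureMiRNA(id=f"m{i}", sequence=s) for i, s in enumerate(tables.table2["mature_seq"])]
clusters = dedupe_unique(matures)
print("unique clusters among the 20 putative novel matures:")
for c in clusters.clusters:
    print(f"  {c.cluster_id}: {c.representative}  ({c.size} members)")

tree = "(((t1:1,t2:1):1,(t3:1,t4:1):1):1,((t5:1,t6:1):1,(t7:1,t8:1):1):1);"
rng = np.random.default_rng(0)
low, _ = evolve_family("UUGGCAUUCUGUCCACCUCC", tree, 0.03, seed=1)
high, _ = evolve_family("".join(rng.choice(list("ACGU"), 150)), tree, 0.5, seed=2)
low_ident = pairwise_identity_matrix([(r.id, r.sequence) for r in low])
high_ident = pairwise_identity_matrix([(r.id, r.sequence) for r in high])
d, p = ks_two_sample(low_ident.pair_values, high_ident.pair_values)
print(f"\nfraction of pairs at >= 90% identity:")
print(f"  mature-like family    (rate 0.03): {low_ident.fraction_at(0.90):.3f}")
print(f"  precursor-like family (rate 0.50): {high_ident.fraction_at(0.90):.3f}")
print(f"KS two-sample: D = {d:.3f}, p = {p:.3g} "
      f"(the two conservation regimes are clearly distinct)")
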