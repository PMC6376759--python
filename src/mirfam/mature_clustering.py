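"""Unique-sequence clustering of mature miRNAs and identity-distribution statistics.

Mature sequences that are identical across species collapse into one
"unique" cluster (UmiR set); a small ``bracket_tolerance`` admits clusters
whose members differ at up to that many positions, which is how a printed
representative like ``AGGUGGG[C/U]AUACUGCCAAUA`` arises.  Clustering is
greedy complete-linkage over equal-length sequences, processed by
descending abundance then lexicographic order, so the result is
deterministic and chain-merging of distinct near-neighbour clusters is
avoided.

The identity statistics summarize how conserved a family is: a symmetric
pairwise-identity matrix (pairwise-deletion denominator), its upper-triangle
ECDF, and the fraction of pairs at or above an identity threshold.  A
two-sample Kolmogorov-Smirnov test compares two such identity samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import kolmogorov

from .seqio import MatureMiRNA


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    representative: str
    member_ids: tuple[str, ...]
    member_seqs: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class UniqueClusterSet:
    clusters: tuple[Cluster, ...]
    bracket_tolerance: int

    def __len__(self) -> int:
        return len(self.clusters)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def dedupe_unique(
    seqs: Sequence[MatureMiRNA],
    bracket_tolerance: int = 0,
) -> UniqueClusterSet:
    """Partition mature sequences into unique (near-)identical clusters.

    Two sequences may share a cluster only if they have equal length and
    every pair of members differs at <= ``bracket_tolerance`` positions
    (complete linkage).  Unique sequences are processed by descending
    abundance, ties lexicographic; clusters are numbered ``UmiR-1`` ... by
    descending member count, ties by representative.  The representative is
    the most frequent member sequence, ties lexicographic.
    """
    if any(not s.sequence for s in seqs):
        raise ValueError("empty sequence")
    counts: dict[str, list[str]] = {}
    for s in seqs:
        counts.setdefault(s.sequence, []).append(s.id)
    order = sorted(counts, key=lambda q: (-len(counts[q]), q))

    groups: list[list[str]] = []  # lists of unique sequences
    for seq in order:
        placed = False
        for g in groups:
            if all(len(m) == len(seq) and _hamming(m, seq) <= bracket_tolerance for m in g):
                g.append(seq)
                placed = True
                break
        if not placed:
            groups.append([seq])

    built = []
    for g in groups:
        rep = min(g, key=lambda q: (-len(counts[q]), q))
        ids = tuple(i for q in g for i in counts[q])
        member_seqs = tuple(q for q in g for _ in counts[q])
        built.append((rep, ids, member_seqs))
    built.sort(key=lambda t: (-len(t[1]), t[0]))
    clusters = tuple(
        Cluster(f"UmiR-{k + 1}", rep, ids, mseqs)
        for k, (rep, ids, mseqs) in enumerate(built)
    )
    return UniqueClusterSet(clusters=clusters, bracket_tolerance=bracket_tolerance)


# ---------------------------------------------------------------------------
# identity statistics


@dataclass(frozen=True)
class IdentityDistribution:
    """Pairwise identity fractions of an aligned (or equal-length) family."""

    ids: tuple[str, ...]
    matrix: np.ndarray  # symmetric, diagonal 1

    @property
    def pair_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.matrix[iu]

    def ecdf(self, x: np.ndarray | float) -> np.ndarray | float:
        vals = np.sort(self.pair_values)
        return np.searchsorted(vals, x, side="right") / len(vals)

    def fraction_at(self, threshold: float) -> float:
        """Share of pairs with identity >= threshold."""
        vals = self.pair_values
        return float(np.mean(vals >= threshold))


def pairwise_identity_matrix(
    seqs: Sequence[tuple[str, str]] | Sequence[MatureMiRNA],
) -> IdentityDistribution:
    """Identity fractions over all pairs, with a pairwise-deletion denominator.

    Accepts (id, sequence) pairs or mature records; sequences may carry
    ``-`` gap characters if pre-aligned, otherwise they must be equal
    length.  identity(i, j) = matching columns / columns where both
    sequences are non-gap.
    """
    items = [
        (s.id, s.sequence) if isinstance(s, MatureMiRNA) else (s[0], s[1]) for s in seqs
    ]
    lens = {len(q) for _, q in items}
    if len(lens) > 1:
        raise ValueError("sequences must be pre-aligned or equal length")
    n = len(items)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = items[i][1], items[j][1]
            shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not shared:
                raise ValueError(f"no comparable columns for pair ({items[i][0]}, {items[j][0]})")
            ident = sum(x == y for x, y in shared) / len(shared)
            mat[i, j] = mat[j, i] = ident
    return IdentityDistribution(ids=tuple(i for i, _ in items), matrix=mat)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum of the absolute ECDF difference; the p-value comes
    from the asymptotic Kolmogorov distribution evaluated at
    ``sqrt(n_a n_b / (n_a + n_b)) * D``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    d = float(np.max(np.abs(fa - fb)))
    en = a.size * b.size / (a.size + b.size)
    p = float(kolmogorov(np.sqrt(en) * d))
    return d, min(max(p, 0.0), 1.0)
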