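"""Distance-based phylogenetics: alignment, p-distance, neighbor joining, bootstrap.

The estimator chain mirrors how the family trees were built: sequences are
multiple-aligned (center-star progressive alignment with unit edit costs),
pairwise p-distances are computed under pairwise deletion (each pair's
denominator is the columns where both sequences are non-gap), an unrooted
tree is reconstructed with Saitou-Nei neighbor joining, and edge supports
come from column-resampling bootstrap replicates.

Negative NJ branch-length estimates are clamped to zero with the deficit
moved to the sister branch, keeping all reported lengths non-negative while
preserving the path length through the joined pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import SequenceRecord


class UndefinedDistanceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class CharacterAlignment:
    taxa: tuple[str, ...]
    rows: tuple[str, ...]  # equal-length, over {A,C,G,U,-}

    def __post_init__(self) -> None:
        assert len(self.taxa) == len(set(self.taxa)), "duplicate taxa"
        assert len({len(r) for r in self.rows}) == 1, "rows differ in length"

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, rng: np.random.Generator) -> "CharacterAlignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return CharacterAlignment(self.taxa, rows)


def _pairwise_align(a: str, b: str) -> tuple[str, str]:
    """Global alignment, match 0 / mismatch 1 / gap 1, deterministic."""
    m, n = len(a), len(b)
    D = np.zeros((m + 1, n + 1), dtype=np.int32)
    D[:, 0] = np.arange(m + 1)
    D[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        ai = a[i - 1]
        row, prev = D[i], D[i - 1]
        for j in range(1, n + 1):
            row[j] = min(
                prev[j - 1] + (ai != b[j - 1]),
                prev[j] + 1,
                row[j - 1] + 1,
            )
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i][j] == D[i - 1][j - 1] + (a[i - 1] != b[j - 1]):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and D[i][j] == D[i - 1][j] + 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _edit_distance(a: str, b: str) -> int:
    m, n = len(a), len(b)
    prev = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        cur = np.empty(n + 1, dtype=np.int32)
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(prev[j - 1] + (ai != b[j - 1]), prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev[n])


def align_family(seqs: Sequence[SequenceRecord]) -> CharacterAlignment:
    """Center-star progressive multiple alignment.

    The center is the sequence minimizing the summed pairwise edit distance
    (ties to the first in input order); every other sequence is aligned to
    the center pairwise and the alignments are merged under "once a gap,
    always a gap".  Deterministic; requires >= 2 sequences.
    """
    if len(seqs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    names = [s.id for s in seqs]
    raw = [s.sequence for s in seqs]
    k = len(raw)
    sums = [sum(_edit_distance(raw[i], raw[j]) for j in range(k) if j != i) for i in range(k)]
    center = int(np.argmin(sums))

    master = raw[center]  # center row with accumulated gaps
    others: dict[int, str] = {}
    for idx in range(k):
        if idx == center:
            continue
        ac, ao = _pairwise_align(master.replace("-", ""), raw[idx])
        # re-thread the new pairwise center (ac) through the existing master
        merged_master: list[str] = []
        merged_new: list[str] = []
        pi = 0  # index into ac/ao
        for ch in master:
            if ch == "-":
                merged_master.append("-")
                merged_new.append("-")
            else:
                while ac[pi] == "-":
                    merged_master.append("-")
                    merged_new.append(ao[pi])
                    # a brand-new gap in the center: widen previous rows
                    pos = len(merged_master) - 1
                    for key in others:
                        others[key] = others[key][:pos] + "-" + others[key][pos:]
                    pi += 1
                merged_master.append(ch)
                merged_new.append(ao[pi])
                pi += 1
        while pi < len(ac):  # trailing center gaps
            merged_master.append("-")
            merged_new.append(ao[pi])
            pos = len(merged_master) - 1
            for key in others:
                others[key] = others[key][:pos] + "-" + others[key][pos:]
            pi += 1
        master = "".join(merged_master)
        others[idx] = "".join(merged_new)

    rows = []
    for idx in range(k):
        rows.append(master if idx == center else others[idx])
    return CharacterAlignment(taxa=tuple(names), rows=tuple(rows))


# ---------------------------------------------------------------------------
# distances


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    values: np.ndarray
    comparable_sites: np.ndarray

    def d(self, i: int, j: int) -> float:
        return float(self.values[i, j])


def p_distance_matrix(
    aln: CharacterAlignment,
    site_coverage: float | None = None,
) -> DistanceMatrix:
    """Proportion of differing sites among pairwise-shared (non-gap) columns.

    ``site_coverage`` enables partial deletion: columns with a non-gap
    fraction below the threshold (e.g. 0.95) are dropped globally before
    the pairwise-deletion distances are computed.
    """
    k = len(aln.taxa)
    arr = np.array([list(r) for r in aln.rows])
    if site_coverage is not None:
        keep = (arr != "-").mean(axis=0) >= site_coverage
        if not keep.any():
            raise UndefinedDistanceError("no columns meet the coverage threshold")
        arr = arr[:, keep]
    gaps = arr == "-"
    values = np.zeros((k, k))
    comp = np.zeros((k, k), dtype=int)
    for i in range(k):
        comp[i, i] = int((~gaps[i]).sum())
        for j in range(i + 1, k):
            shared = ~gaps[i] & ~gaps[j]
            n_shared = int(shared.sum())
            comp[i, j] = comp[j, i] = n_shared
            if n_shared == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites for pair ({aln.taxa[i]}, {aln.taxa[j]})"
                )
            diff = int((arr[i][shared] != arr[j][shared]).sum())
            values[i, j] = values[j, i] = diff / n_shared
    return DistanceMatrix(taxa=aln.taxa, values=values, comparable_sites=comp)


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # bootstrap percent for the edge above

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal node as anchor."""

    root: TreeNode
    taxa: tuple[str, ...]

    def newick(self, decimals: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(
                f"{fmt(ch)}:{bl:.{decimals}f}" for ch, bl in node.children
            )
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(n: TreeNode) -> None:
            if n.is_leaf():
                out.append(n.name)
            for ch, _ in n.children:
                walk(ch)

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset[str], tuple[float, float | None]]:
        """Internal-edge bipartitions as the leaf set below the edge, mapped
        to (branch length, support)."""
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset[str], tuple[float, float | None]] = {}

        def walk(n: TreeNode) -> frozenset[str]:
            if n.is_leaf():
                return frozenset([n.name])
            below = frozenset()
            for ch, bl in n.children:
                side = walk(ch)
                if not ch.is_leaf() and 1 < len(side) < len(all_leaves) - 1:
                    out[side] = (bl, ch.support)
                below |= side
            return below

        walk(self.root)
        return out

    def path_distances(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Leaf-to-leaf path-length matrix (additivity check)."""
        leaves = self.leaf_names()
        index = {n: i for i, n in enumerate(leaves)}
        k = len(leaves)
        dist = np.zeros((k, k))

        def walk(n: TreeNode, depth: float, acc: list[tuple[int, float]]) -> list[tuple[int, float]]:
            if n.is_leaf():
                return [(index[n.name], depth)]
            below: list[tuple[int, float]] = []
            groups = []
            for ch, bl in n.children:
                g = walk(ch, depth + bl, acc)
                groups.append(g)
                below.extend(g)
            for ga, gb in itertools.combinations(groups, 2):
                for (ia, da), (ib, db) in itertools.product(ga, gb):
                    d = da + db - 2 * depth
                    dist[ia, ib] = dist[ib, ia] = d
            return below

        walk(self.root, 0.0, [])
        return tuple(leaves), dist


def build_nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Joins are tie-broken toward the lowest (i, j) index pair; the final
    three nodes are connected through one internal node with the closed-form
    branch lengths.  Exact on additive matrices.
    """
    k = len(dm.taxa)
    if k < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    D = dm.values.astype(float).copy()
    active = list(range(k))

    def clamp(pair: list[tuple[TreeNode, float]]) -> list[tuple[TreeNode, float]]:
        (na, la), (nb, lb) = pair
        if la < 0:
            lb, la = lb + la, 0.0
        if lb < 0:
            la, lb = la + lb, 0.0
        return [(na, max(la, 0.0)), (nb, max(lb, 0.0))]

    while len(active) > 3:
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        n_act = len(active)
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (n_act - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n_act - 2))
        lj = D[i, j] - li
        parent = TreeNode(children=clamp([(nodes[i], li), (nodes[j], lj)]))
        new_index = D.shape[0]
        newrow = np.zeros((1, D.shape[1]))
        D = np.vstack([D, newrow])
        D = np.hstack([D, np.zeros((D.shape[0], 1))])
        for m_ in active:
            if m_ in (i, j):
                continue
            D[new_index, m_] = D[m_, new_index] = 0.5 * (D[i, m_] + D[j, m_] - D[i, j])
        nodes.append(parent)
        active = [m_ for m_ in active if m_ not in (i, j)] + [new_index]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    lengths = [la, lb, lc]
    idxs = [a, b, c]
    # clamp negatives, moving each deficit to the longest sister
    for t in range(3):
        if lengths[t] < 0:
            other = max((u for u in range(3) if u != t), key=lambda u: lengths[u])
            lengths[other] += lengths[t]
            lengths[t] = 0.0
    root = TreeNode(children=[(nodes[idxs[t]], max(lengths[t], 0.0)) for t in range(3)])
    return PhyloTree(root=root, taxa=dm.taxa)


def bootstrap_supports(
    aln: CharacterAlignment,
    n_replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Each replicate resamples alignment columns with replacement (seeded),
    recomputes p-distances and an NJ tree, and the support of an internal
    edge is the percentage of replicates containing its bipartition.
    """
    if n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    if aln.n_columns < 2:
        raise ValueError("cannot resample a single-column alignment")
    tree = build_nj_tree(p_distance_matrix(aln))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep = aln.resample_columns(rng)
        try:
            rep_tree = build_nj_tree(p_distance_matrix(rep))
        except UndefinedDistanceError:
            continue
        rep_bps = set(rep_tree.bipartitions())
        all_leaves = frozenset(aln.taxa)
        rep_bps |= {all_leaves - bp for bp in rep_bps}
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    def annotate(n: TreeNode) -> frozenset[str]:
        if n.is_leaf():
            return frozenset([n.name])
        below = frozenset()
        for ch, _ in n.children:
            side = annotate(ch)
            if not ch.is_leaf():
                if side in counts:
                    ch.support = 100.0 * counts[side] / n_replicates
            below |= side
        return below

    annotate(tree.root)
    return tree


def check_bipartition(tree: PhyloTree, group: set[str]) -> tuple[bool, float | None]:
    """Does some internal edge split exactly ``group`` vs the rest?

    Returns (flag, support of the defining edge or None when absent / not
    annotated).
    """
    leaves = set(tree.leaf_names())
    unknown = set(group) - leaves
    if unknown:
        raise ValueError(f"unknown taxa {sorted(unknown)}")
    if not group or group == leaves:
        raise ValueError("group must be a nonempty proper subset of the leaves")
    g = frozenset(group)
    comp = frozenset(leaves) - g
    for bp, (_, support) in tree.bipartitions().items():
        if bp == g or bp == comp:
            return True, support
    return False, None


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (supports as internal-node labels) using dendropy."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            return TreeNode(name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else "")
        node = TreeNode()
        if dnode.label is not None:
            try:
                node.support = float(dnode.label)
            except ValueError:
                pass
        for ch in dnode.child_nodes():
            node.children.append((convert(ch), ch.edge.length or 0.0))
        return node

    root = convert(dtree.seed_node)
    leaves = [lf.taxon.label.replace(" ", "_") for lf in dtree.leaf_node_iter()]
    return PhyloTree(root=root, taxa=tuple(leaves))
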