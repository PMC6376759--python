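"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by enumeration or naive dynamic
programming, sharing no code with the implementation paths they check.
"""

from __future__ import annotations

import functools
import itertools

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def brute_force_scan(query: str, subject: str, max_mm: int) -> set[tuple[int, str, int]]:
    """(start, strand, mismatches) of every window within max_mm, both strands."""
    out = set()
    m = len(query)
    rc = naive_revcomp(query)
    for s in range(len(subject) - m + 1):
        win = subject[s : s + m]
        for strand, q in (("+", query), ("-", rc)):
            mm = sum(a != b or a == "N" for a, b in zip(win, q))
            if mm <= max_mm:
                out.add((s + 1, strand, mm))
    return out


def nussinov_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Plain Nussinov maximum number of canonical pairs (A-U, G-C, G-U)."""
    n = len(seq)
    ok = lambda a, b: {a, b} in ({"A", "U"}, {"G", "C"}, {"G", "U"})
    N = [[0] * n for _ in range(n)]
    for L in range(min_loop + 1, n):
        for i in range(n - L):
            j = i + L
            best = N[i + 1][j]
            if ok(seq[i], seq[j]):
                inner = N[i + 1][j - 1] if i + 1 <= j - 1 else 0
                best = max(best, inner + 1)
            for k in range(i + 1, j):
                best = max(best, N[i][k] + N[k + 1][j])
            N[i][j] = best
    return N[0][n - 1]


def exhaustive_min_penalty(
    mirna: str,
    site: str,
    max_gaps: int | None = 2,
    mismatch: float = 1.0,
    wobble: float = 0.5,
    gap_open: float = 2.0,
    gap_extend: float = 0.5,
    seed: tuple[int, int] = (2, 7),
    seed_mult: float = 1.5,
    scored: int = 20,
) -> float:
    """Minimum total penalty over all global alignments with <= max_gaps
    gap characters (unbounded when None), by exhaustive recursion (affine
    gap runs tracked via the previous move)."""
    if max_gaps is None:
        max_gaps = len(mirna) + len(site)
    y = site[::-1]
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    wob = {("G", "U"), ("U", "G")}

    @functools.lru_cache(maxsize=None)
    def go(i: int, j: int, gaps: int, last: str) -> float:
        if i == len(mirna) and j == len(y):
            return 0.0
        best = float("inf")
        if i < len(mirna) and j < len(y):
            pos = i + 1
            duo = (mirna[i], y[j])
            if pos > scored:
                c = 0.0
            elif duo in wc:
                c = 0.0
            elif duo in wob:
                c = wobble
            else:
                c = mismatch * (seed_mult if seed[0] <= pos <= seed[1] else 1.0)
            best = min(best, c + go(i + 1, j + 1, gaps, "M"))
        if gaps < max_gaps and i < len(mirna):
            pos = i + 1
            c = 0.0 if pos > scored else (gap_extend if last == "X" else gap_open)
            best = min(best, c + go(i + 1, j, gaps + 1, "X"))
        if gaps < max_gaps and j < len(y):
            pos = i + 1
            c = 0.0 if pos > scored else (gap_extend if last == "Y" else gap_open)
            best = min(best, c + go(i, j + 1, gaps + 1, "Y"))
        return best

    result = go(0, 0, 0, "-")
    go.cache_clear()
    return result


def grid_ks_statistic(a, b) -> float:
    """Sup ECDF difference evaluated on a fine grid plus all sample points."""
    pts = sorted(set(a) | set(b))
    d = 0.0
    for x in pts:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        d = max(d, abs(fa - fb))
    return d


def random_additive_tree(rng, n_taxa: int):
    """A random binary tree with positive branch lengths; returns
    (taxa, distance matrix, newick-less node structure as nested tuples)."""
    import numpy as np

    nodes = [(f"t{i}", None) for i in range(n_taxa)]
    lengths = {}
    counter = itertools.count(n_taxa)
    active = list(range(n_taxa))
    parents = {}
    blen = {}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        p = next(counter)
        parents[a] = parents[b] = p
        blen[a] = float(rng.uniform(0.1, 2.0))
        blen[b] = float(rng.uniform(0.1, 2.0))
        active = [x for x in active if x not in (a, b)] + [p]
    root = active[0]

    def path_to_root(x):
        out = []
        while x != root:
            out.append(x)
            x = parents[x]
        return out

    dist = np.zeros((n_taxa, n_taxa))
    for u in range(n_taxa):
        for v in range(u + 1, n_taxa):
            # lowest common ancestor = first shared node on the upward paths
            upward_u = path_to_root(u) + [root]
            upward_v = path_to_root(v) + [root]
            common = next(x for x in upward_v if x in set(upward_u))
            d = sum(blen[x] for x in upward_u[: upward_u.index(common)]) + sum(
                blen[x] for x in upward_v[: upward_v.index(common)]
            )
            dist[u, v] = dist[v, u] = d
    taxa = tuple(f"t{i}" for i in range(n_taxa))
    return taxa, dist
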