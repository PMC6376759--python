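"""Secondary-structure prediction and stem-loop validation of candidate precursors.

The folding engine is a base-pair maximization over the canonical pairs
A-U, G-C and G-U with a minimum hairpin-loop size, breaking ties among
maximum-pair structures toward the one with the most stacked pairs (longer
helices).  Both objectives are solved exactly in a single dynamic program by
scoring each pair at a large fixed weight and each stack at one unit, so the
returned structure always attains the Nussinov pair maximum.

The energy estimate is a deliberately simple additive surrogate (see
:func:`structure_energy`): -2.0 kcal/mol per stacked pair of pairs, -1.0 per
isolated pair, +0.1 per unpaired position enclosed by at least one pair.
It orders hairpins sensibly but is not a thermodynamic (Turner-model)
energy; an external thermodynamic folder can be plugged in wherever a
:class:`SecondaryStructure` is accepted.

Validation applies the family's annotation criteria to a candidate window:
at least 18 of the mature positions paired, the mature arm followed by a
loop on its far side (the "central loop"), the mature lying on a single
unbranched stem, and a surrogate energy below a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .homology_scan import PrecursorWindow

_PAIR_WEIGHT = 1024  # > max possible stacks, makes (pairs, stacks) lexicographic
MIN_LOOP_DEFAULT = 3
ENERGY_CUTOFF_DEFAULT = -15.0
MIN_MATURE_PAIRED = 18

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


class FoldError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free pairing of a window.

    ``pair_table`` is 1-based with 0 meaning unpaired (position ``i`` pairs
    with ``pair_table[i]``); ``dotbracket`` uses the Vienna convention.
    """

    dotbracket: str
    pair_table: tuple[int, ...]  # index 0 unused
    energy_estimate: float
    n_pairs: int

    def __post_init__(self) -> None:
        pt = self.pair_table
        assert len(pt) == len(self.dotbracket) + 1
        for i in range(1, len(pt)):
            if pt[i]:
                assert pt[pt[i]] == i, "pair table not symmetric"

    def partner(self, i: int) -> int:
        """1-based partner of 1-based position i (0 if unpaired)."""
        return self.pair_table[i]


@dataclass(frozen=True)
class HairpinReport:
    mature_paired: int
    has_central_loop: bool
    single_stem: bool
    energy_estimate: float
    verdict: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def _fill_kernel_py(code, n, min_loop, F, FNP, P):
    for L in range(1, n + 1):
        for i in range(n - L + 1):
            j = i + L - 1
            # P: (i, j) paired
            a, b = code[i], code[j]
            ok = (a == 0 and b == 3) or (a == 3 and b == 0) or \
                 (a == 1 and b == 2) or (a == 2 and b == 1) or \
                 (a == 2 and b == 3) or (a == 3 and b == 2)
            if ok and j - i - 1 >= min_loop:
                inner = FNP[i + 1, j - 1]
                if P[i + 1, j - 1] >= 0 and P[i + 1, j - 1] + 1 > inner:
                    inner = P[i + 1, j - 1] + 1
                P[i, j] = _PAIR_WEIGHT + inner
            else:
                P[i, j] = -1
            # FNP: best over [i, j] without pairing i to j
            best = F[i + 1, j] if i + 1 <= j else 0
            for k in range(i + min_loop + 1, j):
                if P[i, k] >= 0:
                    cand = P[i, k] + (F[k + 1, j] if k + 1 <= j else 0)
                    if cand > best:
                        best = cand
            FNP[i, j] = best
            F[i, j] = max(best, P[i, j])


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _fill_kernel = njit(cache=True)(_fill_kernel_py)
except Exception:  # pragma: no cover
    _fill_kernel = _fill_kernel_py


def _fill(code: np.ndarray, min_loop: int):
    n = len(code)
    F = np.zeros((n + 1, n + 1), dtype=np.int32)
    FNP = np.zeros((n + 1, n + 1), dtype=np.int32)
    P = np.full((n + 1, n + 1), -1, dtype=np.int32)
    _fill_kernel(code, n, min_loop, F, FNP, P)
    return F, FNP, P


def _traceback(n, min_loop, F, FNP, P) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    stack = [("F", 0, n - 1)]
    while stack:
        state, i, j = stack.pop()
        if i >= j:
            continue
        if state == "F":
            if P[i, j] >= 0 and P[i, j] == F[i, j]:
                stack.append(("P", i, j))
            else:
                stack.append(("N", i, j))
        elif state == "N":
            skip = F[i + 1, j] if i + 1 <= j else 0
            if skip == FNP[i, j]:
                stack.append(("F", i + 1, j))
                continue
            for k in range(i + min_loop + 1, j):
                if P[i, k] >= 0 and P[i, k] + F[k + 1, j] == FNP[i, j]:
                    stack.append(("P", i, k))
                    stack.append(("F", k + 1, j))
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed")
        else:  # P
            pairs.append((i, j))
            inner = P[i, j] - _PAIR_WEIGHT
            if P[i + 1, j - 1] >= 0 and P[i + 1, j - 1] + 1 == inner:
                stack.append(("P", i + 1, j - 1))
            elif inner > 0:
                stack.append(("N", i + 1, j - 1))
    return pairs


def structure_energy(pair_table: tuple[int, ...]) -> float:
    """Additive surrogate energy of a pairing (see module docstring)."""
    n = len(pair_table) - 1
    stacks = 0
    isolated = 0
    for i in range(1, n + 1):
        j = pair_table[i]
        if j > i:
            stacked_in = i + 1 <= n and pair_table[i + 1] == j - 1 and j - 1 > i + 1
            stacked_out = i - 1 >= 1 and pair_table[i - 1] == j + 1
            if stacked_in:
                stacks += 1
            if not stacked_in and not stacked_out:
                isolated += 1
    enclosed_unpaired = 0
    depth = 0
    for i in range(1, n + 1):
        j = pair_table[i]
        if j > i:
            depth += 1
        elif j and j < i:
            depth -= 1
        elif depth > 0:
            enclosed_unpaired += 1
    return -2.0 * stacks - 1.0 * isolated + 0.1 * enclosed_unpaired


def fold_structure(window_seq: str, min_loop: int = MIN_LOOP_DEFAULT) -> SecondaryStructure:
    """Deterministic maximum-pair fold of a window.

    Raises :class:`FoldError` on windows shorter than ``2 * min_loop``.
    The returned pair count equals the Nussinov maximum for the same
    minimum-loop constraint.
    """
    n = len(window_seq)
    if n < 2 * min_loop:
        raise FoldError(f"window of {n} nt too short to fold (min_loop={min_loop})")
    code = np.array([_ENC[c] for c in window_seq], dtype=np.int8)
    F, FNP, P = _fill(code, min_loop)
    pairs = _traceback(n, min_loop, F, FNP, P)
    pt = [0] * (n + 1)
    db = ["."] * n
    for i, j in pairs:
        pt[i + 1] = j + 1
        pt[j + 1] = i + 1
        db[i] = "("
        db[j] = ")"
    pt_t = tuple(pt)
    return SecondaryStructure(
        dotbracket="".join(db),
        pair_table=pt_t,
        energy_estimate=structure_energy(pt_t),
        n_pairs=len(pairs),
    )


def _hairpin_loops(pt: tuple[int, ...]) -> list[tuple[int, int]]:
    """1-based (start, end) spans of hairpin loops: maximal unpaired runs
    directly closed by a pair."""
    n = len(pt) - 1
    loops = []
    for i in range(1, n + 1):
        j = pt[i]
        if j > i and all(pt[k] == 0 for k in range(i + 1, j)):
            loops.append((i + 1, j - 1))
    return loops


def _mature_stems(
    pt: tuple[int, ...], span: range
) -> list[list[tuple[int, int]]]:
    """Group the pairs of mature positions into unbranched stems.

    Two consecutive paired mature positions stay in one stem when their
    partners lie on the same side of the mature, nest properly, and nothing
    else is paired in the bulges between them (no multiloop branch).
    """
    pairs = [(k, pt[k]) for k in span if pt[k]]
    stems: list[list[tuple[int, int]]] = []
    for k, q in pairs:
        if stems:
            k0, q0 = stems[-1][-1]
            same_side = (q < span.start) == (q0 < span.start)
            bulge = list(range(k0 + 1, k)) + list(range(min(q0, q) + 1, max(q0, q)))
            if same_side and all(pt[p] == 0 for p in bulge):
                stems[-1].append((k, q))
                continue
        stems.append([(k, q)])
    return stems


def validate_precursor(
    window: PrecursorWindow,
    structure: SecondaryStructure,
    energy_cutoff: float = ENERGY_CUTOFF_DEFAULT,
    min_mature_paired: int = MIN_MATURE_PAIRED,
) -> HairpinReport:
    """Apply the stem-loop annotation criteria to a folded candidate window.

    Pass requires: >= ``min_mature_paired`` mature positions paired, a
    hairpin loop entirely beyond the mature arm whose enclosing helix pairs
    with the mature (the central loop), the mature crossing no multiloop
    branch (single stem), and surrogate energy <= ``energy_cutoff``.
    """
    n = len(window.window_seq)
    mlen = window.locus.end - window.locus.start + 1
    off = window.mature_offset
    if not 0 <= off <= n - mlen:
        raise ConsistencyError(f"mature_offset {off} out of bounds for {n}-nt window")
    if len(structure.dotbracket) != n:
        raise ConsistencyError("structure was not computed on this window")

    pt = structure.pair_table
    span = range(off + 1, off + mlen + 1)  # 1-based mature positions
    span_set = set(span)
    reasons: list[str] = []

    mature_pairs = [(k, pt[k]) for k in span if pt[k]]
    mature_paired = len(mature_pairs)
    if mature_paired < min_mature_paired:
        reasons.append(f"mature pairing {mature_paired} < {min_mature_paired}")

    # single stem: the mature's pairing must be carried by one unbranched
    # stem.  Pair maximization routinely strands a position or two in
    # co-optimal side pairs, so the criterion grants the same slack as the
    # pairing count: all but (mature length - min_mature_paired) of the
    # paired mature positions must sit in one stem.
    stems = _mature_stems(pt, span)
    dominant = max(stems, key=len) if stems else []
    slack = max(0, mlen - min_mature_paired)
    single = bool(dominant) and mature_paired - len(dominant) <= slack
    if not single:
        reasons.append("mature region crosses a multiloop branch")

    # central loop: beyond the mature arm, the dominant stem must close on
    # loop structure that lies entirely outside the mature span (a hairpin
    # loop there; incidental pairs inside that loop region are tolerated)
    central = False
    if dominant:
        # innermost pair: largest k when the partner arm is 3' of the
        # mature, smallest k when it is 5'
        inner_k, inner_q = dominant[-1] if dominant[0][1] > span.start else dominant[0]
        lo, hi = min(inner_k, inner_q), max(inner_k, inner_q)
        central = any(
            lo < a and b < hi and not any(p in span_set for p in range(a, b + 1))
            for a, b in _hairpin_loops(pt)
        )
    if not central:
        reasons.append("no central loop beyond mature")

    energy = structure.energy_estimate
    if energy > energy_cutoff:
        reasons.append(f"energy {energy:.1f} above cutoff {energy_cutoff:.1f}")

    verdict = mature_paired >= min_mature_paired and central and single and energy <= energy_cutoff
    return HairpinReport(
        mature_paired=mature_paired,
        has_central_loop=central,
        single_stem=single,
        energy_estimate=energy,
        verdict=verdict,
        reasons=tuple(reasons),
    )


def _subwindow(window: PrecursorWindow, a: int, b: int) -> PrecursorWindow:
    """A trimmed copy of a window; [a, b) must still contain the mature."""
    mlen = window.locus.end - window.locus.start + 1
    assert a <= window.mature_offset and window.mature_offset + mlen <= b
    return PrecursorWindow(
        locus=window.locus,
        window_seq=window.window_seq[a:b],
        mature_offset=window.mature_offset - a,
        provenance=f"{window.provenance}[{a}:{b}]",
    )


def best_precursor_report(
    window: PrecursorWindow,
    energy_cutoff: float = ENERGY_CUTOFF_DEFAULT,
    min_mature_paired: int = MIN_MATURE_PAIRED,
    min_loop: int = MIN_LOOP_DEFAULT,
    trim_step: int = 4,
    min_extension: int = 16,
) -> tuple[HairpinReport, PrecursorWindow]:
    """Validate a scan window by proposing precursor candidates inside it.

    A fixed symmetric window around a homology hit is a search window, not
    a precursor: the complementary arm lies on one (unknown) side and the
    rest is genomic context whose base pairing can drown the hairpin under
    pair maximization.  This proposal stage therefore folds one-sided
    candidates — the mature plus a growing 3' extension, then plus a
    growing 5' extension, finally the full window — and returns the first
    candidate whose structure passes :func:`validate_precursor`.  When none
    passes, the full-window report is returned.

    Deterministic; the candidate that validated is returned alongside the
    report so callers can record the proposed precursor coordinates.
    """
    mlen = window.locus.end - window.locus.start + 1
    off = window.mature_offset
    n = len(window.window_seq)
    right_avail = n - off - mlen
    left_avail = off

    candidates: list[tuple[int, int]] = []
    for t in range(min_extension, right_avail + 1, trim_step):
        candidates.append((off, off + mlen + t))
    if right_avail >= min_extension and (right_avail - min_extension) % trim_step:
        candidates.append((off, n))
    for t in range(min_extension, left_avail + 1, trim_step):
        candidates.append((off - t, off + mlen))
    if left_avail >= min_extension and (left_avail - min_extension) % trim_step:
        candidates.append((0, off + mlen))
    candidates.append((0, n))

    fallback: tuple[HairpinReport, PrecursorWindow] | None = None
    for a, b in candidates:
        sub = _subwindow(window, a, b)
        if len(sub.window_seq) < 2 * min_loop:
            continue
        report = validate_precursor(
            sub,
            fold_structure(sub.window_seq, min_loop=min_loop),
            energy_cutoff=energy_cutoff,
            min_mature_paired=min_mature_paired,
        )
        if report.verdict:
            return report, sub
        if (a, b) == (0, n):
            fallback = (report, sub)
    assert fallback is not None
    return fallback
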