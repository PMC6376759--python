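"""Penalty-based scoring of miRNA:target-site duplexes and inhibition-mode calls.

A candidate site is scored by globally aligning the miRNA (5'->3') against
the site read 3'->5' (the antiparallel duplex) and summing per-position
penalties in the psRNATarget/miRU convention:

* Watson-Crick pair: 0
* G:U wobble (either orientation): 0.5 (never seed-multiplied)
* mismatch: 1.0, multiplied by 1.5 at seed positions (miRNA 2-7)
* gap: 2.0 to open, 0.5 per extension

Only the first 20 miRNA positions (5'-anchored) are scored; longer miRNAs
contribute nothing past position 20.  The total is the expectation score E
(0 = perfect complement; lower is better), and sites with E above a cutoff
(default 5) are discarded.  A duplex disrupted at the central positions
9-11 (mismatch or bulge) is called translational inhibition; otherwise the
site is called a cleavage target.

The alignment is an affine-gap (Gotoh) dynamic program; ties are broken
toward fewer gaps, then the leftmost gap placement, so results are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .seqio import MatureMiRNA, SequenceRecord

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

INF = float("inf")


@dataclass(frozen=True)
class PenaltyScheme:
    """Weights of the expectation score.  All penalties are >= 0."""

    mismatch: float = 1.0
    wobble: float = 0.5
    gap_open: float = 2.0
    gap_extend: float = 0.5
    seed_start: int = 2
    seed_end: int = 7
    seed_multiplier: float = 1.5  # applied to mismatches only
    scored_window: int = 20  # miRNA positions 1..20, 5'-anchored
    max_e: float = 5.0
    central_positions: tuple[int, ...] = (9, 10, 11)

    def __post_init__(self) -> None:
        if min(self.mismatch, self.wobble, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be >= 0")
        if not (1 <= self.seed_start <= self.seed_end <= self.scored_window):
            raise ValueError("seed range must lie inside the scored window")

    def in_seed(self, pos: int) -> bool:
        return self.seed_start <= pos <= self.seed_end

    def substitution(self, pos: int, mir_base: str, site_base: str) -> tuple[str, float]:
        """(state, penalty) for miRNA position ``pos`` paired with a site base."""
        if pos > self.scored_window:
            return "unscored", 0.0
        duo = (mir_base, site_base)
        if duo in _WC:
            return "WC", 0.0
        if duo in _WOBBLE:
            return "wobble", self.wobble
        pen = self.mismatch * (self.seed_multiplier if self.in_seed(pos) else 1.0)
        return "mismatch", pen

    def gap_cost(self, pos: int, opening: bool) -> float:
        """Cost of a gap attributed to miRNA position ``pos`` (0 past the window)."""
        if pos > self.scored_window:
            return 0.0
        return self.gap_open if opening else self.gap_extend

    def edit_penalty(self, kind: str, pos: int) -> float:
        """Penalty a single engineered edit contributes (recipe arithmetic)."""
        if pos > self.scored_window:
            return 0.0
        if kind == "mismatch":
            return self.mismatch * (self.seed_multiplier if self.in_seed(pos) else 1.0)
        if kind == "wobble":
            return self.wobble
        if kind in ("gap_target", "gap_mirna"):
            return self.gap_open
        raise ValueError(f"unknown edit kind {kind!r}")


@dataclass(frozen=True)
class TargetAlignment:
    """A scored antiparallel duplex.

    ``states[i]`` is the pairing state of miRNA position ``i+1`` (one of
    WC / wobble / mismatch / gap-target / unscored; gap-target means the
    miRNA base bulges against a gap in the site).  ``insertions`` records
    site bases bulged against the miRNA as (miRNA position preceding the
    bulge, site base).  ``E`` is the summed penalty.
    """

    mirna_id: str
    mirna_seq: str
    site_seq: str  # 5'->3' on the transcript
    states: tuple[str, ...]
    per_position_penalty: tuple[float, ...]
    insertions: tuple[tuple[int, str], ...]
    insertion_penalties: tuple[float, ...]
    E: float
    start: int = 0  # 1-based transcript coordinate when produced by a scan
    end: int = 0
    upe_proxy: float | None = None

    def __post_init__(self) -> None:
        total = sum(self.per_position_penalty) + sum(self.insertion_penalties)
        assert abs(total - self.E) < 1e-9, "E must equal the summed penalties"


def min_penalty_alignment(
    mirna: MatureMiRNA | str,
    site: str,
    scheme: PenaltyScheme = PenaltyScheme(),
) -> TargetAlignment:
    """Minimum-penalty global antiparallel alignment of a miRNA and a site.

    The site is given 5'->3' as it appears on the transcript; internally it
    is reversed so the miRNA 5' end faces the site 3' end.  Site length must
    be within 2 of the scored miRNA length on the short side and of the full
    miRNA length on the long side.
    """
    mid, mseq = (mirna.id, mirna.sequence) if isinstance(mirna, MatureMiRNA) else ("query", mirna)
    m = len(mseq)
    scored_len = min(m, scheme.scored_window)
    if not scored_len - 2 <= len(site) <= m + 2:
        raise ValueError(
            f"site length {len(site)} outside [{scored_len - 2}, {m + 2}]"
        )
    y = site[::-1]  # 3'->5', faces miRNA 5'->3'
    n = len(y)

    # Gotoh: M diagonal, X = gap in site (miRNA base bulged, "gap-target"),
    # Y = gap in miRNA (site base bulged)
    M = [[INF] * (n + 1) for _ in range(m + 1)]
    X = [[INF] * (n + 1) for _ in range(m + 1)]
    Y = [[INF] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    if m >= 1:
        X[1][0] = scheme.gap_cost(1, True)
        for i in range(2, m + 1):
            X[i][0] = X[i - 1][0] + scheme.gap_cost(i, False)
    # leading site overhang bulges before miRNA position 1
    if n >= 1:
        Y[0][1] = scheme.gap_cost(1, True)
        for j in range(2, n + 1):
            Y[0][j] = Y[0][j - 1] + scheme.gap_cost(1, False)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            _, sub = scheme.substitution(i, mseq[i - 1], y[j - 1])
            M[i][j] = sub + min(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = min(
                M[i - 1][j] + scheme.gap_cost(i, True),
                X[i - 1][j] + scheme.gap_cost(i, False),
                Y[i - 1][j] + scheme.gap_cost(i, True),
            )
            # bulged site base sits after miRNA position i
            Y[i][j] = min(
                M[i][j - 1] + scheme.gap_cost(i + 1, True),
                Y[i][j - 1] + scheme.gap_cost(i + 1, False),
                X[i][j - 1] + scheme.gap_cost(i + 1, True),
            )

    # traceback, preferring diagonal, then site-gap, then miRNA-gap
    i, j = m, n
    finals = {"M": M[m][n], "X": X[m][n], "Y": Y[m][n]}
    state = min(finals, key=lambda s: (finals[s], "MXY".index(s)))
    E = finals[state]
    states = ["unscored"] * m
    penalties = [0.0] * m
    insertions: list[tuple[int, str]] = []
    ins_pens: list[float] = []
    while i > 0 or j > 0:
        if state == "M":
            st, pen = scheme.substitution(i, mseq[i - 1], y[j - 1])
            states[i - 1] = st
            penalties[i - 1] = pen
            prevs = {"M": M[i - 1][j - 1], "X": X[i - 1][j - 1], "Y": Y[i - 1][j - 1]}
            target = M[i][j] - pen
            state = min(
                (s for s in "MXY" if abs(prevs[s] - target) < 1e-9),
                key="MXY".index,
            )
            i, j = i - 1, j - 1
        elif state == "X":
            open_c = scheme.gap_cost(i, True)
            ext_c = scheme.gap_cost(i, False)
            states[i - 1] = "gap-target" if i <= scheme.scored_window else "unscored"
            if abs(X[i - 1][j] + ext_c - X[i][j]) < 1e-9:
                penalties[i - 1] = ext_c
                state = "X"
            elif abs(M[i - 1][j] + open_c - X[i][j]) < 1e-9:
                penalties[i - 1] = open_c
                state = "M"
            else:
                penalties[i - 1] = open_c
                state = "Y"
            i -= 1
        else:  # Y: site base bulged after miRNA position i
            open_c = scheme.gap_cost(i + 1, True)
            ext_c = scheme.gap_cost(i + 1, False)
            prev_m = M[i][j - 1]
            prev_y = Y[i][j - 1]
            prev_x = X[i][j - 1] if i > 0 else INF
            if abs(prev_y + ext_c - Y[i][j]) < 1e-9:
                pen, state = ext_c, "Y"
            elif abs(prev_m + open_c - Y[i][j]) < 1e-9:
                pen, state = open_c, "M"
            else:
                assert abs(prev_x + open_c - Y[i][j]) < 1e-9
                pen, state = open_c, "X"
            insertions.append((i, y[j - 1]))
            ins_pens.append(pen)
            j -= 1
    return TargetAlignment(
        mirna_id=mid,
        mirna_seq=mseq,
        site_seq=site,
        states=tuple(states),
        per_position_penalty=tuple(penalties),
        insertions=tuple(reversed(insertions)),
        insertion_penalties=tuple(reversed(ins_pens)),
        E=round(E, 6),
    )


def classify_inhibition(
    alignment: TargetAlignment,
    scheme: PenaltyScheme = PenaltyScheme(),
) -> str:
    """Cleavage unless the central region (miRNA 9-11) is disrupted.

    Disruption means a mismatch or a bulge at a central position; wobbles
    and Watson-Crick pairs there leave the duplex cleavable.  A site base
    bulged strictly inside the central region (between positions 9-10 or
    10-11) also counts as disruption.
    """
    lo, hi = min(scheme.central_positions), max(scheme.central_positions)
    for pos in scheme.central_positions:
        if pos <= len(alignment.states) and alignment.states[pos - 1] in (
            "mismatch",
            "gap-target",
        ):
            return "Translation"
    for after_pos, _ in alignment.insertions:
        if lo <= after_pos < hi:
            return "Translation"
    return "Cleavage"


@dataclass(frozen=True)
class TranscriptHit:
    alignment: TargetAlignment
    transcript_id: str
    start: int  # 1-based inclusive
    end: int
    inhibition: str


def scan_transcript(
    mirna: MatureMiRNA | str,
    transcript: SequenceRecord,
    scheme: PenaltyScheme = PenaltyScheme(),
) -> list[TranscriptHit]:
    """Scan a transcript for target sites of a miRNA.

    Every window of length len-2 ... len+2 around each start is scored; at
    each start the best window is kept, then non-overlapping hits with
    E <= ``scheme.max_e`` are reported, sorted by (E, position).
    """
    mseq = mirna.sequence if isinstance(mirna, MatureMiRNA) else mirna
    m = len(mseq)
    scored_len = min(m, scheme.scored_window)
    tseq = transcript.sequence

    def n_gaps(aln: TargetAlignment) -> int:
        return len(aln.insertions) + sum(s == "gap-target" for s in aln.states)

    candidates: list[tuple[float, int, int, int, TargetAlignment]] = []
    for start in range(len(tseq)):
        best: TargetAlignment | None = None
        for L in range(scored_len - 2, m + 3):
            if start + L > len(tseq):
                break
            aln = min_penalty_alignment(mirna, tseq[start : start + L], scheme)
            if best is None or (aln.E, n_gaps(aln)) < (best.E, n_gaps(best)):
                best = aln
        if best is not None and best.E <= scheme.max_e:
            candidates.append(
                (best.E, n_gaps(best), start + 1, start + len(best.site_seq), best)
            )
    # ties go to the more compact duplex (fewer bulges), then position
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    chosen: list[tuple[float, int, int, int, TargetAlignment]] = []
    for cand in candidates:
        if all(cand[3] < c[2] or cand[2] > c[3] for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: (c[0], c[2]))
    return [
        TranscriptHit(
            alignment=aln,
            transcript_id=transcript.id,
            start=s,
            end=e,
            inhibition=classify_inhibition(aln, scheme),
        )
        for (E, g, s, e, aln) in chosen
    ]


def upe_proxy(transcript_seq: str, start: int, end: int, flank: int = 17) -> float:
    """Accessibility surrogate: mean paired fraction of the site +/- flank
    under the package's fold, scaled to a kcal/mol-like magnitude.

    Reported for orientation only; it is not comparable to partition-function
    unpaired energies and is never used for filtering by default.
    """
    from .hairpin import fold_structure

    a = max(0, start - 1 - flank)
    b = min(len(transcript_seq), end + flank)
    region = transcript_seq[a:b]
    structure = fold_structure(region)
    site_pos = range(start - a, end - a + 1)
    paired = sum(1 for p in site_pos if structure.pair_table[p])
    return round(25.0 * paired / len(structure.dotbracket), 3)
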