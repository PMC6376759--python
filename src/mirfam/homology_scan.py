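"""Locate mature-miRNA homologs in nucleotide sequences and cut precursor windows.

The discovery stage of the annotation workflow: a double-strand k-mismatch
(Hamming) scan of arbitrary subjects for a mature query, followed by
extraction of a candidate precursor window of at most ``max_window``
nucleotides around each hit, and a pluggable exclusion screen standing in
for external tRNA/rRNA scanners.

The default is an exact (zero-mismatch) scan, matching how the family was
annotated; a ``max_mismatches`` knob generalizes it for cross-species search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .seqio import AlphabetError, MatureMiRNA, SequenceRecord, reverse_complement

DEFAULT_MAX_WINDOW = 170
DEFAULT_FLANK = 75

_ENC = {c: i for i, c in enumerate("ACGUN")}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class LocusHit:
    """A query occurrence, always reported in forward-strand coordinates
    (1-based, inclusive).  ``matched_text`` is oriented to the query."""

    subject_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    matched_text: str


@dataclass(frozen=True)
class PrecursorWindow:
    """A candidate precursor: the window sequence oriented 5'->3' on the
    mature strand, with the mature embedded at ``mature_offset`` (0-based)."""

    locus: LocusHit
    window_seq: str
    mature_offset: int
    provenance: str

    def __post_init__(self) -> None:
        m = self.locus.end - self.locus.start + 1
        assert self.window_seq[self.mature_offset : self.mature_offset + m] == (
            self.locus.matched_text
        ), "window does not contain the oriented mature at mature_offset"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def scan_for_mature(
    query: MatureMiRNA | str,
    subject: SequenceRecord,
    max_mismatches: int = 0,
) -> list[LocusHit]:
    """All windows of the subject (both strands) within ``max_mismatches``
    Hamming distance of the query, sorted by (start, strand).

    Coordinates are forward-strand, 1-based, inclusive; a minus-strand hit at
    forward positions [s, e] means the reverse complement of that slice
    matches the query.  ``N`` never matches and is rejected in the query.
    """
    qseq = query.sequence if isinstance(query, MatureMiRNA) else query
    if "N" in qseq:
        raise AlphabetError("degenerate N in query")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    m, n = len(qseq), len(subject.sequence)
    if m > n:
        return []

    subj = _encode(subject.sequence)
    hits: list[LocusHit] = []
    for strand, q in (("+", qseq), ("-", reverse_complement(qseq))):
        qarr = _encode(q)
        mism = np.zeros(n - m + 1, dtype=np.int32)
        for j in range(m):
            mism += subj[j : n - m + 1 + j] != qarr[j]
        # N in the subject is counted as a mismatch against any base
        for s in np.flatnonzero(mism <= max_mismatches):
            s = int(s)
            text = subject.sequence[s : s + m]
            hits.append(
                LocusHit(
                    subject_id=subject.id,
                    start=s + 1,
                    end=s + m,
                    strand=strand,
                    mismatches=int(mism[s]),
                    matched_text=text if strand == "+" else reverse_complement(text),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def extract_precursor_window(
    hit: LocusHit,
    subject: SequenceRecord,
    flank_up: int = DEFAULT_FLANK,
    flank_down: int = DEFAULT_FLANK,
    max_window: int = DEFAULT_MAX_WINDOW,
) -> PrecursorWindow:
    """Cut the candidate precursor window around a hit.

    Flanks are measured in the mature's own 5'->3' orientation, so for a
    minus-strand hit ``flank_up`` extends toward higher forward coordinates
    and the returned window is the reverse complement of the forward slice.
    The window is clipped at subject boundaries and ``mature_offset`` is
    adjusted accordingly.
    """
    if flank_up < 0 or flank_down < 0:
        raise ConfigurationError("flanks must be >= 0")
    qlen = hit.end - hit.start + 1
    if flank_up + qlen + flank_down > max_window:
        raise ConfigurationError(
            f"window {flank_up}+{qlen}+{flank_down} exceeds max_window={max_window}"
        )
    n = len(subject.sequence)
    if hit.strand == "+":
        a = max(1, hit.start - flank_up)
        b = min(n, hit.end + flank_down)
        window = subject.sequence[a - 1 : b]
        offset = hit.start - a
    else:
        a = max(1, hit.start - flank_down)
        b = min(n, hit.end + flank_up)
        window = reverse_complement(subject.sequence[a - 1 : b])
        offset = b - hit.end
    return PrecursorWindow(
        locus=hit,
        window_seq=window,
        mature_offset=offset,
        provenance=f"{subject.id}:{a}-{b}({hit.strand})",
    )


# ---------------------------------------------------------------------------
# exclusion screen

Predicate = Callable[[PrecursorWindow], bool]


@dataclass
class ScreenResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def low_complexity(window: PrecursorWindow, max_frac: float = 0.80) -> bool:
    """Fires when any single nucleotide exceeds ``max_frac`` of the window."""
    seq = window.window_seq
    return any(seq.count(c) > max_frac * len(seq) for c in "ACGU")


def tandem_repeat(window: PrecursorWindow, max_motif: int = 6, max_cover: float = 0.60) -> bool:
    """Fires when a tandem run of one motif (<= ``max_motif`` nt) covers more
    than ``max_cover`` of the window."""
    seq = window.window_seq
    n = len(seq)
    for k in range(1, max_motif + 1):
        for start in range(n - 2 * k + 1):
            motif = seq[start : start + k]
            run = k
            while start + run + k <= n and seq[start + run : start + run + k] == motif:
                run += k
            if run > k and run > max_cover * n:
                return True
    return False


BUILTIN_PREDICATES: tuple[Predicate, ...] = (low_complexity, tandem_repeat)


def screen_candidate(
    window: PrecursorWindow,
    predicates: Sequence[Predicate] = BUILTIN_PREDICATES,
) -> ScreenResult:
    """Apply exclusion predicates in order; fail iff any fires.

    External tRNA/rRNA scanners attach through this interface as extra
    callables.  A predicate that raises is recorded under ``errors`` and the
    window is kept (screening errs on the side of retention).
    """
    result = ScreenResult(passed=True)
    for pred in predicates:
        name = getattr(pred, "__name__", repr(pred))
        try:
            if pred(window):
                result.passed = False
                result.reasons.append(name)
        except Exception as exc:  # noqa: BLE001 - reported per predicate
            result.errors.append(f"{name}: {exc}")
    return result
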