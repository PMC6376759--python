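"""Ground-truthed synthetic inputs for every stage of the annotation pipeline.

Three generators emulate the data the analysis consumes, each emitting a
manifest (:class:`GroundTruth`) that later stages can be checked against:

* :func:`simulate_family` — a mature-sequence family diverged from a root
  20-mer along a known tree, one substitution process per branch (each site
  changes with probability ``1 - exp(-rate * branch_length)``, jumping to a
  uniformly chosen different base).
* :func:`synthesize_genome` — a uniform-random genome carrying implanted
  hairpin precursors (mature + loop + mutated reverse-complement arm, random
  strand) plus decoys that are dinucleotide-preserving shuffles of such
  units: same composition and dinucleotide content, no planted hairpin, so
  the discovery pipeline should emit no validated window at a decoy locus.
* :func:`synthesize_transcripts` — transcripts carrying target sites built
  by editing the perfect complement according to penalty recipes, with the
  intended expectation score recorded per site.

All generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import MatureMiRNA, SequenceRecord, reverse_complement
from .target_scoring import PenaltyScheme

DEFAULT_MATURE = "UUGGCAUUCUGUCCACCUCC"
_BASES = np.array(list("ACGU"))

# a 10-leaf family tree used when none is supplied
DEFAULT_FAMILY_TREE = (
    "(((t1:0.3,t2:0.3):0.4,(t3:0.2,t4:0.5):0.3):0.3,"
    "((t5:0.4,t6:0.2):0.5,(t7:0.3,(t8:0.2,t9:0.2):0.3):0.4):0.2,t10:0.8);"
)


class CapacityError(RuntimeError):
    pass


class RecipeError(ValueError):
    pass


@dataclass(frozen=True)
class Edit:
    """One engineered deviation from the perfect complement of a site."""

    kind: str  # mismatch | wobble | gap_target | gap_mirna
    mirna_pos: int  # 1-based, 5' anchored


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 42
    genome_length: int = 8000
    n_hairpin_implants: int = 19
    n_decoys: int = 19
    mature_seq: str = DEFAULT_MATURE
    loop_length: int = 8
    arm_mutation_rate: float = 0.0
    family_tree: str = DEFAULT_FAMILY_TREE
    family_site_rate: float = 0.05
    transcript_specs: tuple[tuple[int, tuple[Edit, ...]], ...] = (
        (300, ()),  # perfect site
        (300, (Edit("mismatch", 14),)),
        (300, (Edit("gap_target", 10),)),
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.arm_mutation_rate <= 1.0:
            raise ValueError("rates must be within [0, 1]")
        if self.genome_length < self.n_hairpin_implants * 200:
            raise ValueError("genome_length must be >= 200 per implant")


@dataclass
class GroundTruth:
    """Manifest of everything the generators planted."""

    implants: list[dict] = field(default_factory=list)
    decoys: list[dict] = field(default_factory=list)
    transcript_sites: list[dict] = field(default_factory=list)
    family_tree: str = ""
    branch_substitutions: dict = field(default_factory=dict)
    leaf_sequences: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# family simulation


def evolve_family(
    root_seq: str,
    newick: str,
    site_rate: float,
    seed: int,
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Diverge a root sequence along a Newick tree.

    Each branch substitutes every site independently with probability
    ``1 - exp(-site_rate * branch_length)``; a substitution picks one of the
    three other bases uniformly.  Seeded and reproducible; works for any
    root sequence (mature-sized or precursor-sized).
    """
    from .phylo import parse_newick

    tree = parse_newick(newick)
    rng = np.random.default_rng(seed)
    truth = GroundTruth(family_tree=newick)
    leaves: list[SequenceRecord] = []

    def evolve(seq: str, bl: float, label: str) -> str:
        p = 1.0 - np.exp(-site_rate * bl)
        chars = list(seq)
        n_subs = 0
        for k in range(len(chars)):
            if rng.random() < p:
                alternatives = [b for b in "ACGU" if b != chars[k]]
                chars[k] = alternatives[rng.integers(0, 3)]
                n_subs += 1
        truth.branch_substitutions[label] = truth.branch_substitutions.get(label, 0) + n_subs
        return "".join(chars)

    counter = [0]

    def walk(node, seq: str) -> None:
        if node.is_leaf():
            truth.leaf_sequences[node.name] = seq
            leaves.append(SequenceRecord(id=node.name, sequence=seq))
            return
        for child, bl in node.children:
            counter[0] += 1
            label = child.name or f"branch{counter[0]}"
            walk(child, evolve(seq, bl, label))

    walk(tree.root, root_seq)
    return leaves, truth


def simulate_family(spec: SyntheticSpec) -> tuple[list[MatureMiRNA], GroundTruth]:
    """Diverge the root mature sequence along ``spec.family_tree``.

    A thin wrapper over :func:`evolve_family` returning mature-miRNA records
    (the root must be mature-sized, 18-25 nt).
    """
    leaves, truth = evolve_family(
        spec.mature_seq, spec.family_tree, spec.family_site_rate, spec.seed
    )
    return [MatureMiRNA(id=r.id, sequence=r.sequence) for r in leaves], truth


# ---------------------------------------------------------------------------
# genome synthesis


def _mutate_arm(arm: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(arm)
    for k in range(len(chars)):
        if rng.random() < rate:
            chars[k] = [b for b in "ACGU" if b != chars[k]][rng.integers(0, 3)]
    return "".join(chars)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 200) -> str:
    """A uniform-ish dinucleotide-preserving shuffle (Eulerian-walk resampling)."""
    if len(seq) < 3:
        return seq
    for _ in range(max_tries):
        edges: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            edges.setdefault(a, []).append(b)
        for lst in edges.values():
            order = rng.permutation(len(lst))
            lst[:] = [lst[t] for t in order]
        out = [seq[0]]
        ok = True
        for _ in range(len(seq) - 1):
            lst = edges.get(out[-1])
            if not lst:
                ok = False
                break
            out.append(lst.pop(0))
        if ok:
            return "".join(out)
    return seq  # degenerate composition; identity is a valid shuffle


def _hairpin_unit(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[str, int]:
    """(unit sequence, mature offset inside the unit)."""
    loop = "".join(rng.choice(_BASES, size=spec.loop_length))
    arm = _mutate_arm(reverse_complement(spec.mature_seq), spec.arm_mutation_rate, rng)
    return spec.mature_seq + loop + arm, 0


def _decoy_unit(spec: SyntheticSpec, rng: np.random.Generator) -> str:
    unit, _ = _hairpin_unit(spec, rng)
    return dinucleotide_shuffle(unit, rng)


def synthesize_genome(spec: SyntheticSpec) -> tuple[SequenceRecord, GroundTruth]:
    """Uniform-random genome with hairpin implants and shuffled decoys.

    Units are embedded at non-overlapping positions (>= 30 nt apart) on a
    random strand; the manifest records, for every unit, the forward-strand
    coordinates of the embedded mature (1-based inclusive) and its strand.
    Raises :class:`CapacityError` if placement fails after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    genome = list(rng.choice(_BASES, size=spec.genome_length))
    truth = GroundTruth()
    taken: list[tuple[int, int]] = []
    mlen = len(spec.mature_seq)

    def place(unit: str) -> tuple[int, str]:
        for _ in range(1000):
            pos = int(rng.integers(0, spec.genome_length - len(unit)))
            if all(pos + len(unit) + 30 <= a or pos >= b + 30 for a, b in taken):
                taken.append((pos, pos + len(unit)))
                strand = "+" if rng.random() < 0.5 else "-"
                inserted = unit if strand == "+" else reverse_complement(unit)
                genome[pos : pos + len(unit)] = list(inserted)
                return pos, strand
        raise CapacityError("could not place unit without overlap")

    for k in range(spec.n_hairpin_implants):
        unit, moff = _hairpin_unit(spec, rng)
        pos, strand = place(unit)
        if strand == "+":
            m_start = pos + moff + 1
        else:
            m_start = pos + len(unit) - moff - mlen + 1
        truth.implants.append(
            {
                "id": f"implant{k + 1}",
                "unit_start": pos + 1,
                "unit_end": pos + len(unit),
                "mature_start": m_start,
                "mature_end": m_start + mlen - 1,
                "strand": strand,
            }
        )
    for k in range(spec.n_decoys):
        unit = _decoy_unit(spec, rng)
        pos, strand = place(unit)
        truth.decoys.append(
            {
                "id": f"decoy{k + 1}",
                "unit_start": pos + 1,
                "unit_end": pos + len(unit),
                "strand": strand,
            }
        )
    record = SequenceRecord(id=f"synthetic_genome_seed{spec.seed}", sequence="".join(genome))
    return record, truth


# ---------------------------------------------------------------------------
# transcript synthesis


def build_site(
    mature: str,
    edits: Sequence[Edit],
    scheme: PenaltyScheme = PenaltyScheme(),
) -> tuple[str, float]:
    """Edit the perfect complement of the scored miRNA window per recipe.

    Returns the site (5'->3') and the intended expectation score, computed
    from the scheme's penalty arithmetic.  Recipes may carry at most one gap
    of each kind and must name positions inside the miRNA.
    """
    scored = mature[: scheme.scored_window]
    site = list(reverse_complement(scored))
    L = len(site)
    intended = 0.0
    if sum(e.kind.startswith("gap") for e in edits) > 2:
        raise RecipeError("too many gap edits")
    # apply substitutions first, then gaps (right-to-left to keep indices valid)
    subs = [e for e in edits if e.kind in ("mismatch", "wobble")]
    gaps = [e for e in edits if e.kind.startswith("gap")]
    for e in subs:
        if not 1 <= e.mirna_pos <= len(mature):
            raise RecipeError(f"position {e.mirna_pos} outside the miRNA")
        idx = L - e.mirna_pos  # site index pairing this miRNA position
        if idx < 0:
            raise RecipeError("edit beyond the scored window has no site base")
        base = mature[e.mirna_pos - 1]
        if e.kind == "wobble":
            if base == "G":
                site[idx] = "U"
            elif base == "U":
                site[idx] = "G"
            else:
                raise RecipeError(f"no wobble partner for {base} at position {e.mirna_pos}")
        else:
            wc = reverse_complement(base)
            choices = [b for b in "ACGU" if b != wc and (base, b) not in (("G", "U"), ("U", "G"))]
            site[idx] = choices[0]
        intended += scheme.edit_penalty(e.kind, e.mirna_pos)
    for e in sorted(gaps, key=lambda e: -e.mirna_pos):
        if not 1 <= e.mirna_pos <= len(mature):
            raise RecipeError(f"position {e.mirna_pos} outside the miRNA")
        idx = L - e.mirna_pos
        if e.kind == "gap_target":
            del site[idx]  # miRNA base left bulged
        else:  # gap_mirna: extra site base bulged after this miRNA position
            bulge = "C" if mature[e.mirna_pos - 1] not in "CG" else "A"
            site.insert(idx + 1, bulge)
        intended += scheme.edit_penalty(e.kind, e.mirna_pos)
    return "".join(site), intended


def synthesize_transcripts(
    spec: SyntheticSpec,
    scheme: PenaltyScheme = PenaltyScheme(),
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Random transcripts, each carrying one engineered site mid-sequence."""
    rng = np.random.default_rng(spec.seed + 1)
    truth = GroundTruth()
    records = []
    for t, (length, edits) in enumerate(spec.transcript_specs):
        site, intended = build_site(spec.mature_seq, edits, scheme)
        if length < len(site) + 20:
            raise ValueError("transcript too short for its site")
        seq = list(rng.choice(_BASES, size=length))
        pos = int(rng.integers(10, length - len(site) - 10))
        seq[pos : pos + len(site)] = list(site)
        rec = SequenceRecord(id=f"transcript{t + 1}", sequence="".join(seq))
        records.append(rec)
        truth.transcript_sites.append(
            {
                "transcript_id": rec.id,
                "start": pos + 1,
                "end": pos + len(site),
                "site": site,
                "intended_e": intended,
                "edits": [(e.kind, e.mirna_pos) for e in edits],
            }
        )
    return records, truth
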