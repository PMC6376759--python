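"""Sequence I/O, alphabet normalization, and the packaged family tables.

The package works on a single canonical alphabet, RNA ``{A, C, G, U, N}``.
DNA input is converted on read (``T`` -> ``U``) when RNA mode is requested,
because genomic subjects arrive as DNA while mature miRNAs are RNA.

Three tab-separated tables ship with the package: the per-species census of
registered mature miR394s (5p/3p arm counts), the twenty novel stem-loop
precursors with their genomic windows and reported minimum free energies,
and the unique-mature-sequence clusters with their predicted target sites,
expectation scores and inhibition modes.  They are loaded through
:func:`load_fixtures` and verified against a row-count/checksum manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class FormatError(ValueError):
    """Malformed FASTA input."""


class AlphabetError(ValueError):
    """Sequence contains characters outside the canonical RNA alphabet."""


class FixtureIntegrityError(RuntimeError):
    """Packaged table does not match its manifest."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the canonical RNA alphabet."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r} contains non-RNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature small RNA with miRBase-style name, species prefix and arm.

    The arm is read off the identifier: names ending in ``-3p`` are 3p
    products, names ending in ``-5p`` are explicitly 5p, anything else is
    recorded as ``5p`` as well since unsuffixed names denote the 5' product
    in this family.
    """

    id: str
    sequence: str
    species_code: str = ""
    arm: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise AlphabetError(f"{self.id!r}: non-RNA characters {sorted(bad)}")
        if not 18 <= len(self.sequence) <= 25:
            raise ValueError(
                f"{self.id!r}: mature length {len(self.sequence)} outside [18, 25]"
            )
        if not self.species_code:
            object.__setattr__(self, "species_code", self.id.split("-", 1)[0])
        if not self.arm:
            object.__setattr__(self, "arm", "3p" if self.id.endswith("-3p") else "5p")

    def __len__(self) -> int:
        return len(self.sequence)


def normalize(seq: str, rna: bool = True) -> str:
    """Uppercase and, in RNA mode, rewrite T as U; reject anything else."""
    s = seq.upper()
    if rna:
        s = s.replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-alphabet characters {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Antiparallel complement of an RNA string (N maps to N)."""
    bad = set(seq.upper()) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-alphabet characters {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, rna: bool = True) -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Order is preserved; sequences are uppercased and T->U normalized when
    ``rna`` is true.  A header without sequence, or sequence data before the
    first header, raises :class:`FormatError` naming the offending record.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"record {header!r} has no sequence")
        ident, _, desc = header.partition(" ")
        records.append(SequenceRecord(ident, normalize(seq, rna=rna), desc))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError("empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"sequence data before first header: {line[:30]!r}")
                chunks.append(line)
    flush()
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# packaged tables


@dataclass(frozen=True)
class FixtureTables:
    """The three packaged tables as pandas DataFrames.

    ``table1``: per-species counts of registered mature sequences by arm.
    ``table2``: novel precursor windows (gene id, coordinates, MFE, mature).
    ``table3``: unique-mature clusters, their unique target sites (UTS),
    expectation scores, target accessions and inhibition modes.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def unique_matures(self) -> list[tuple[str, str]]:
        """(cluster id, representative sequence) pairs, brackets expanded to
        their first-listed variant (e.g. ``[C/U]`` -> ``C``)."""
        out = []
        for _, row in self.table3.drop_duplicates("cluster").iterrows():
            seq = row["unique_seq"]
            while "[" in seq:
                a = seq.index("[")
                b = seq.index("]")
                seq = seq[:a] + seq[a + 1] + seq[b + 1 :]
            out.append((f"UmiR394-{row['cluster']}", seq))
        return out


def _data_path(name: str):
    return resources.files("mirfam").joinpath("data", name)


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def load_fixtures(verify: bool = True) -> FixtureTables:
    """Load the packaged tables, verifying row counts and checksums.

    The two rows of table 2 whose printed values are internally inconsistent
    (a 173-nt window against the 170-nt cap, and a mature sequence that
    contradicts its cluster assignment) are stored as printed and surfaced
    in :attr:`FixtureTables.flags`.
    """
    raw = {n: _data_path(n).read_text() for n in ("table1.tsv", "table2.tsv", "table3.tsv")}
    manifest = json.loads(_data_path("manifest.json").read_text())
    tables = {}
    for name, text in raw.items():
        if verify:
            n_rows = text.count("\n") - 1
            if n_rows != manifest[name]["rows"]:
                raise FixtureIntegrityError(
                    f"{name}: {n_rows} rows, manifest says {manifest[name]['rows']}"
                )
            if _sha256(text) != manifest[name]["sha256"]:
                raise FixtureIntegrityError(f"{name}: checksum mismatch")
        key = name.split(".")[0]
        tables[key] = pd.read_csv(
            _data_path(name).open(), sep="\t", dtype=str, keep_default_na=False
        )

    t1 = tables["table1"].astype({"n_5p": int, "n_3p": int, "total": int})
    if not (t1["n_5p"] + t1["n_3p"] == t1["total"]).all():
        raise FixtureIntegrityError("table1: arm counts do not sum to totals")

    t2 = tables["table2"].astype({"start": int, "end": int, "mfe_kcal_mol": float})
    if not (t2["mfe_kcal_mol"] < 0).all():
        raise FixtureIntegrityError("table2: non-negative MFE")

    t3 = tables["table3"].copy()
    t3["evalue"] = pd.to_numeric(t3["evalue"].replace("NA", None))
    t3["upe"] = pd.to_numeric(t3["upe"].replace("NA", None))
    # carry cluster metadata down the denormalized rows
    t3["cluster"] = t3["cluster"].astype(int)
    for col in ("mir_ids", "unique_seq"):
        t3[col] = t3[col].replace("", None)
        t3[col] = t3.groupby("cluster")[col].ffill()
    if (t3["evalue"].dropna() < 0).any():
        raise FixtureIntegrityError("table3: negative expectation score")
    modes = set(t3["inhibition"]) - {"Cleavage", "Translation", "NA"}
    if modes:
        raise FixtureIntegrityError(f"table3: unknown inhibition modes {modes}")

    flags = {
        row["mir_id"]: row["flag"]
        for _, row in t2.iterrows()
        if row.get("flag")
    }
    return FixtureTables(table1=t1, table2=t2, table3=t3, flags=flags)


def iter_uts_rows(tables: FixtureTables) -> Iterator[dict]:
    """One entry per distinct UTS (16 in the packaged table): the mature
    sequence, site sequence, printed expectation score and inhibition mode."""
    seen = set()
    for _, row in tables.table3.iterrows():
        uid = row["uts_id"]
        if uid == "NA" or uid in seen:
            continue
        seen.add(uid)
        yield {
            "uts_id": uid,
            "cluster": row["cluster"],
            "mature_seq": _expand_first(row["unique_seq"]),
            "uts_seq": row["uts_seq"],
            "evalue": float(row["evalue"]),
            "inhibition": row["inhibition"],
        }


def _expand_first(seq: str) -> str:
    while "[" in seq:
        a, b = seq.index("["), seq.index("]")
        seq = seq[:a] + seq[a + 1] + seq[b + 1 :]
    return seq
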