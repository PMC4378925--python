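"""Protein sequence databases and composite-database construction.

Secretome MS/MS searches are only as good as the database searched: a human
cell secretome prepared in fetal bovine serum (FBS) contains bovine
contaminant proteins, so the search database must be a *composite* of the
human proteome and the expected contaminants.  This module models FASTA
protein databases as first-class objects with provenance, and provides the
constructors for the composite databases used in contaminant-aware
secretome analysis:

* a human proteome database,
* a full bovine proteome database,
* an FBS database -- the subset of the bovine proteome actually observed in
  serum profiling experiments,
* a human+bovine composite (whole-proteome merge), and
* a human+FBS composite (human proteome plus only the profiled FBS
  sequences),

optionally extended with a small set of utility sequences (proteases used
for digestion and mass standards) that downstream species censuses track in
a separate bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .errors import AccessionCollisionError, DuplicateAccessionError, FastaParseError

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: UniProt realism: ambiguity codes, selenocysteine and translation stops occur.
TOLERATED_AA = frozenset("BJXZU")


class Species(str, Enum):
    """Origin of a protein record; `utility` marks proteases/standards."""

    HUMAN = "human"
    BOVINE = "bovine"
    UTILITY = "utility"


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry with its species and provenance annotation."""

    accession: str
    description: str
    species: Species
    sequence: str
    source_db: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        if not self.sequence.isupper():
            raise ValueError(f"{self.accession}: sequence must be uppercase")
        extra = set(self.sequence) - STANDARD_AA - TOLERATED_AA
        if extra:
            raise ValueError(
                f"{self.accession}: invalid residues {sorted(extra)} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class SequenceDatabase:
    """An ordered, accession-unique collection of :class:`ProteinRecord`.

    ``components`` records provenance as ``(source name, record count)``
    pairs; when a database is built by concatenation without deduplication
    the entry count equals the sum of the component counts.
    """

    def __init__(
        self,
        name: str,
        records: Iterable[ProteinRecord] = (),
        components: Sequence[tuple[str, int]] | None = None,
    ) -> None:
        self.name = name
        self._records: list[ProteinRecord] = []
        self._by_accession: dict[str, ProteinRecord] = {}
        for rec in records:
            if rec.accession in self._by_accession:
                raise DuplicateAccessionError(
                    f"duplicate accession {rec.accession!r} in database {name!r}"
                )
            self._records.append(rec)
            self._by_accession[rec.accession] = rec
        if components is None:
            components = _components_from_records(self._records)
        self.components: list[tuple[str, int]] = list(components)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SequenceDatabase({self.name!r}, {len(self)} records)"

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self._records]

    def get(self, accession: str) -> ProteinRecord:
        return self._by_accession[accession]

    def species_map(self) -> dict[str, Species]:
        """Accession -> species lookup for downstream census classification."""
        return {r.accession: r.species for r in self._records}


def _components_from_records(
    records: Sequence[ProteinRecord],
) -> list[tuple[str, int]]:
    order: list[str] = []
    counts: dict[str, int] = {}
    for rec in records:
        if rec.source_db not in counts:
            order.append(rec.source_db)
            counts[rec.source_db] = 0
        counts[rec.source_db] += 1
    return [(name, counts[name]) for name in order]


def parse_accession(header: str) -> tuple[str, str]:
    """Split a FASTA header line (without '>') into (accession, description).

    For UniProt-style ``db|ACC|NAME desc`` headers the accession is the
    middle pipe-delimited field; otherwise it is the first
    whitespace-delimited token.
    """
    token, _, rest = header.partition(" ")
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1], rest
    return token, rest


def read_fasta(
    path: str | Path,
    species: Species,
    source: str | None = None,
) -> SequenceDatabase:
    """Read a FASTA file into a :class:`SequenceDatabase`.

    One record per entry, in file order.  Trailing ``*`` stop characters are
    stripped; ambiguity codes (B, J, X, Z, U) are tolerated with a warning.
    Raises :class:`FastaParseError` for entries with empty sequences and
    :class:`DuplicateAccessionError` for repeated accessions.
    """
    path = Path(path)
    source = source if source is not None else path.stem
    species = Species(species)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, entry in enumerate(SeqIO.parse(str(path), "fasta")):
        header = entry.description
        accession, description = parse_accession(header)
        if not accession:
            raise FastaParseError(f"{path.name}: entry {i} has a malformed header")
        seq = str(entry.seq).upper().strip("*")
        if not seq:
            raise FastaParseError(
                f"{path.name}: entry {i} ({header!r}) has an empty sequence"
            )
        if "*" in seq:
            warnings.warn(
                f"{accession}: internal stop character '*' removed", stacklevel=2
            )
            seq = seq.replace("*", "")
        odd = set(seq) & TOLERATED_AA
        if odd:
            warnings.warn(
                f"{accession}: non-standard residues {sorted(odd)} tolerated",
                stacklevel=2,
            )
        if accession in seen:
            raise DuplicateAccessionError(
                f"{path.name}: duplicate accession {accession!r}"
            )
        seen.add(accession)
        records.append(
            ProteinRecord(accession, description, species, seq, source)
        )
    return SequenceDatabase(source, records, components=[(source, len(records))])


def write_fasta(db: SequenceDatabase, path: str | Path, width: int = 60) -> None:
    """Write ``db`` as FASTA with ``accession description`` headers."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in db:
            header = rec.accession
            if rec.description:
                header += f" {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def merge_databases(
    parts: Sequence[SequenceDatabase],
    name: str,
    on_collision: str = "suffix",
) -> SequenceDatabase:
    """Concatenate databases in argument order into a composite.

    The entry count of the result is the sum of the part counts and the
    provenance records every part.  Accession collisions across parts are
    resolved per ``on_collision``:

    * ``"suffix"`` (default): the later record is kept under
      ``ACC_sourcedb`` so no entry is silently dropped;
    * ``"error"``: raise :class:`AccessionCollisionError` listing the
      colliding accessions.
    """
    if on_collision not in ("suffix", "error"):
        raise ValueError(f"unknown collision policy {on_collision!r}")
    seen: set[str] = set()
    collisions: list[str] = []
    records: list[ProteinRecord] = []
    for part in parts:
        for rec in part:
            acc = rec.accession
            if acc in seen:
                collisions.append(acc)
                if on_collision == "error":
                    continue
                new_acc = f"{acc}_{rec.source_db}"
                k = 2
                while new_acc in seen:
                    new_acc = f"{acc}_{rec.source_db}{k}"
                    k += 1
                rec = ProteinRecord(
                    new_acc, rec.description, rec.species, rec.sequence, rec.source_db
                )
                acc = new_acc
            seen.add(acc)
            records.append(rec)
    if collisions and on_collision == "error":
        raise AccessionCollisionError(
            f"accession collisions while merging into {name!r}: "
            + ", ".join(sorted(set(collisions)))
        )
    components = [c for part in parts for c in part.components]
    return SequenceDatabase(name, records, components=components)


def build_fbs_database(
    full_bovine: SequenceDatabase,
    fbs_accessions: Sequence[str],
    name: str = "FBS",
    strict: bool = False,
) -> SequenceDatabase:
    """Subset the bovine proteome to the accessions observed in FBS profiling.

    Records are emitted in list order.  Accessions absent from
    ``full_bovine`` are excluded with a warning (``strict=True`` raises
    instead).
    """
    records: list[ProteinRecord] = []
    missing: list[str] = []
    for acc in fbs_accessions:
        if acc in full_bovine:
            records.append(full_bovine.get(acc))
        else:
            missing.append(acc)
    if missing:
        msg = (
            f"{len(missing)} accession(s) absent from {full_bovine.name!r}: "
            + ", ".join(missing[:10])
        )
        if strict:
            raise KeyError(msg)
        warnings.warn(msg, stacklevel=2)
    return SequenceDatabase(
        name, records, components=[(full_bovine.name, len(records))]
    )


def append_utility_sequences(
    db: SequenceDatabase,
    utilities: SequenceDatabase,
    on_collision: str = "suffix",
) -> SequenceDatabase:
    """Append utility sequences (proteases, mass standards) to a database.

    Utility records must carry ``species == Species.UTILITY``; downstream
    species censuses count PSMs matching only utility accessions in a
    separate bin rather than as human or bovine.
    """
    for rec in utilities:
        if rec.species is not Species.UTILITY:
            raise ValueError(
                f"utility record {rec.accession!r} has species {rec.species.value!r}"
            )
    return merge_databases([db, utilities], db.name, on_collision=on_collision)


def read_accession_list(path: str | Path) -> list[str]:
    """Read a plain-text accession list: one per line, '#' starts a comment."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.append(entry)
    return out


def default_utility_database() -> SequenceDatabase:
    """The packaged 20-entry utility database (proteases and mass standards).

    The entries are *synthetic placeholder* sequences standing in for the
    proteases commonly added during sample preparation (trypsin,
    chymotrypsin, Arg-C, Lys-C, Asp-N and their fragments) and yeast
    enolase mass standards; they carry ``Species.UTILITY`` so they are
    never counted as human or bovine identifications.
    """
    ref = resources.files("contamsort") / "data" / "utility_sequences_synthetic.fasta"
    with resources.as_file(ref) as p:
        return read_fasta(p, Species.UTILITY, source="utilities")
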