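"""In-silico tryptic digestion and the cross-species peptide index.

Shotgun proteomics identifies peptides, not proteins, and a peptide whose
exact sequence occurs in proteins of more than one species (an
*orthologous* or shared peptide) cannot attribute its spectrum to either
species.  This module digests whole proteomes in silico with trypsin and
builds an index from each tryptic peptide to its parent proteins and
species, which is the substrate for classifying peptides as human-unique,
bovine-unique or shared.

Digestion follows the classic trypsin rule: cleavage C-terminal to K or R,
suppressed when the next residue is proline (configurable), full enzymatic
specificity only, with up to ``max_missed_cleavages`` internal missed
sites.  Because CID fragmentation cannot distinguish isoleucine from
leucine, the index can optionally fold I onto L so that species-specificity
conclusions can be checked under both conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .sequence_db import SequenceDatabase, Species


@dataclass(frozen=True)
class DigestionParams:
    """Parameters of the in-silico digest.

    Defaults: trypsin with two missed cleavages (matching common search
    settings), peptide length 6..50 residues (typical observable range),
    proline-rule suppression on, no I/L folding.
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 50
    cleave_before_proline: bool = False
    equate_il: bool = False

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("require 0 < min_length <= max_length")

    def canonical(self, peptide: str) -> str:
        """Canonical form of a peptide under the I/L convention."""
        return peptide.replace("I", "L") if self.equate_il else peptide


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide occupying ``[start, start+len)`` of its parent."""

    sequence: str
    start: int
    missed_cleavages: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


class PeptideClass(str, Enum):
    HUMAN_UNIQUE = "human_unique"
    BOVINE_UNIQUE = "bovine_unique"
    SHARED = "shared"
    UTILITY_ONLY = "utility_only"
    UNKNOWN = "unknown"


def cleavage_sites(sequence: str, cleave_before_proline: bool = False) -> list[int]:
    """0-based positions i such that the bond after residue i is cleavable."""
    last = len(sequence) - 1
    return [
        i
        for i in range(last)
        if sequence[i] in "KR"
        and (cleave_before_proline or sequence[i + 1] != "P")
    ]


def digest(sequence: str, params: DigestionParams = DigestionParams()) -> list[Peptide]:
    """All fully-tryptic peptides of ``sequence`` under ``params``.

    Returns peptides ordered by (start, end), each with its internal
    missed-cleavage count; the protein N- and C-terminal peptides are
    included.  Ambiguous residues pass through unchanged.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    sites = cleavage_sites(sequence, params.cleave_before_proline)
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    out: list[Peptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + params.max_missed_cleavages, len(bounds))):
            start, end = bounds[i], bounds[j]
            if params.min_length <= end - start <= params.max_length:
                out.append(Peptide(sequence[start:end], start, j - i - 1))
    return out


class PeptideIndex:
    """Map from canonical peptide sequence to its ``(accession, species)`` parents."""

    def __init__(self, params: DigestionParams = DigestionParams()) -> None:
        self.params = params
        self._entries: dict[str, set[tuple[str, Species]]] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, peptide: str) -> bool:
        return self.params.canonical(peptide) in self._entries

    def add(self, peptide: str, accession: str, species: Species) -> None:
        key = self.params.canonical(peptide)
        self._entries.setdefault(key, set()).add((accession, Species(species)))

    def parents(self, peptide: str) -> frozenset[tuple[str, Species]]:
        return frozenset(self._entries.get(self.params.canonical(peptide), ()))

    def species(self, peptide: str) -> frozenset[Species]:
        return frozenset(s for _, s in self.parents(peptide))

    def peptides(self) -> Iterable[str]:
        return self._entries.keys()

    def shared_peptides(self) -> list[str]:
        """Peptides whose parents span both human and bovine proteins."""
        both = {Species.HUMAN, Species.BOVINE}
        return sorted(
            p for p, par in self._entries.items() if both <= {s for _, s in par}
        )


def build_index(
    dbs: Sequence[SequenceDatabase],
    params: DigestionParams = DigestionParams(),
) -> PeptideIndex:
    """Digest every protein of every database and index the union."""
    index = PeptideIndex(params)
    for db in dbs:
        for rec in db:
            for pep in digest(rec.sequence, params):
                index.add(pep.sequence, rec.accession, rec.species)
    return index


def classify_peptide(peptide: str, index: PeptideIndex) -> PeptideClass:
    """Species-specificity class of one peptide sequence.

    ``SHARED`` whenever the parent species include both human and bovine,
    irrespective of which protein a search engine reported; ``UNKNOWN`` for
    peptides no indexed protein can produce.
    """
    species = index.species(peptide)
    if not species:
        return PeptideClass.UNKNOWN
    if {Species.HUMAN, Species.BOVINE} <= species:
        return PeptideClass.SHARED
    if Species.HUMAN in species:
        return PeptideClass.HUMAN_UNIQUE
    if Species.BOVINE in species:
        return PeptideClass.BOVINE_UNIQUE
    return PeptideClass.UTILITY_ONLY


def write_index(index: PeptideIndex, path: str | Path) -> None:
    """Persist an index as TSV: peptide, comma-joined ``accession|species``."""
    with Path(path).open("w") as fh:
        fh.write(f"# equate_il={int(index.params.equate_il)}\n")
        fh.write("peptide\tparents\n")
        for pep in sorted(index.peptides()):
            parents = ",".join(
                f"{acc}|{sp.value}" for acc, sp in sorted(index.parents(pep))
            )
            fh.write(f"{pep}\t{parents}\n")


def read_index(path: str | Path) -> PeptideIndex:
    lines = Path(path).read_text().splitlines()
    equate_il = False
    if lines and lines[0].startswith("#"):
        equate_il = "equate_il=1" in lines[0]
        lines = lines[1:]
    index = PeptideIndex(DigestionParams(equate_il=equate_il))
    for line in lines[1:]:  # skip header
        pep, _, parents = line.partition("\t")
        for parent in parents.split(","):
            acc, _, sp = parent.partition("|")
            index.add(pep, acc, Species(sp))
    return index
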