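"""PSM table parsing, confidence filtering, protein grouping and q-values.

A peptide-spectrum match (PSM) is one search-engine assignment of a peptide
to an MS/MS spectrum, scored by XCorr (SEQUEST cross-correlation), a
q-value (minimal FDR at which the PSM is accepted) and a posterior error
probability (PEP).  This module consumes PSM tables exported from a search
platform as delimited text and applies the standard post-processing steps:

* confidence filtering with ``q <= 0.01``, charge-dependent XCorr
  thresholds and a top-rank requirement;
* parsimonious protein grouping (minimal set of proteins explaining the
  observed peptides, proteins with identical peptide evidence merged);
* a plain target-decoy q-value estimator used to score synthetic data
  end-to-end (production searches bring their own q-values).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import MissingColumnError, NoDecoysError
from .modifications import Modification, format_modifications, parse_modifications
from .sequence_db import Species

# ---------------------------------------------------------------------------
# data model


@dataclass(frozen=True)
class PSM:
    """One peptide-spectrum match with its scores and protein assignments."""

    spectrum_file: str
    scan: int
    charge: int
    rank: int
    peptide: str
    modifications: tuple[Modification, ...]
    xcorr: float
    q_value: float | None
    pep: float | None
    proteins: tuple[str, ...]
    search_db: str = ""
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"scan {self.scan}: charge must be >= 1")
        if self.rank < 1:
            raise ValueError(f"scan {self.scan}: rank must be >= 1")
        if self.q_value is not None and not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"scan {self.scan}: q_value outside [0, 1]")
        if self.pep is not None and not (0.0 < self.pep <= 1.0):
            raise ValueError(f"scan {self.scan}: pep outside (0, 1]")
        for mod in self.modifications:
            if mod.position is not None and not (0 <= mod.position < len(self.peptide)):
                raise ValueError(
                    f"scan {self.scan}: modification position {mod.position} "
                    f"outside peptide of length {len(self.peptide)}"
                )

    @property
    def spectrum_key(self) -> tuple[str, int]:
        """Spectrum identity for cross-database joins: (file, scan).

        Charge is deliberately excluded so a re-search of the same spectrum
        under another database joins even if the charge call differs.
        """
        return (self.spectrum_file, self.scan)


class PSMSet:
    """An ordered collection of PSMs from one search."""

    def __init__(self, psms: Iterable[PSM] = (), search_db: str = "") -> None:
        self.psms: list[PSM] = list(psms)
        self.search_db = search_db or (self.psms[0].search_db if self.psms else "")

    def __len__(self) -> int:
        return len(self.psms)

    def __iter__(self) -> Iterator[PSM]:
        return iter(self.psms)

    def __getitem__(self, i):
        return self.psms[i]

    def targets(self) -> "PSMSet":
        return PSMSet([p for p in self.psms if not p.is_decoy], self.search_db)

    def decoys(self) -> "PSMSet":
        return PSMSet([p for p in self.psms if p.is_decoy], self.search_db)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.psms:
            rows.append(
                {
                    "spectrum_file": p.spectrum_file,
                    "scan": p.scan,
                    "charge": p.charge,
                    "rank": p.rank,
                    "peptide": p.peptide,
                    "modifications": format_modifications(list(p.modifications)),
                    "xcorr": p.xcorr,
                    "q_value": p.q_value,
                    "pep": p.pep,
                    "proteins": ";".join(p.proteins),
                    "search_db": p.search_db,
                    "is_decoy": int(p.is_decoy),
                }
            )
        return pd.DataFrame(rows)


#: generic-dialect column names (the native TSV layout of this package)
GENERIC_COLUMNS = (
    "spectrum_file",
    "scan",
    "charge",
    "rank",
    "peptide",
    "modifications",
    "xcorr",
    "q_value",
    "pep",
    "proteins",
    "search_db",
)

#: vendor spreadsheet-export column names mapped onto the generic model
PD_EXPORT_COLUMNS: dict[str, str] = {
    "Spectrum File": "spectrum_file",
    "First Scan": "scan",
    "Charge": "charge",
    "Rank": "rank",
    "Sequence": "peptide",
    "Modifications": "modifications",
    "XCorr": "xcorr",
    "Percolator q-Value": "q_value",
    "Percolator PEP": "pep",
    "Protein Accessions": "proteins",
}

_REQUIRED = ("spectrum_file", "scan", "charge", "peptide", "xcorr", "proteins")


def read_psm_table(
    path: str | Path,
    dialect: str = "generic",
    search_db: str | None = None,
) -> PSMSet:
    """Read a delimited PSM table (one PSM per row) into a :class:`PSMSet`.

    ``dialect`` is ``"generic"`` (native TSV columns) or ``"pd_export"``
    (vendor spreadsheet export, comma- or tab-separated, with columns such
    as "First Scan" and "Percolator q-Value").  Missing required columns
    raise :class:`MissingColumnError` naming the column; unparsable
    modification cells raise with the offending row number.  Score columns
    (``q_value``, ``pep``) may be absent -- downstream steps that need them
    raise explicitly rather than defaulting.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else None
    df = pd.read_csv(path, sep=sep, engine="python")
    if dialect == "pd_export":
        df = df.rename(columns=PD_EXPORT_COLUMNS)
        protein_sep = ";"
    elif dialect == "generic":
        protein_sep = ";"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in _REQUIRED:
        if col not in df.columns:
            raise MissingColumnError(f"{path.name}: missing required column {col!r}")

    psms: list[PSM] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        mods = parse_modifications(
            str(row["modifications"]) if "modifications" in row and pd.notna(row["modifications"]) else None,
            row=i + 2,  # 1-based, after the header line
        )
        q = row.get("q_value")
        pep = row.get("pep")
        proteins = tuple(
            t.strip() for t in str(row["proteins"]).split(protein_sep) if t.strip()
        )
        psms.append(
            PSM(
                spectrum_file=str(row["spectrum_file"]),
                scan=int(row["scan"]),
                charge=int(row["charge"]),
                rank=int(row.get("rank", 1)) if pd.notna(row.get("rank", 1)) else 1,
                peptide=str(row["peptide"]).upper(),
                modifications=tuple(mods),
                xcorr=float(row["xcorr"]),
                q_value=float(q) if q is not None and pd.notna(q) else None,
                pep=float(pep) if pep is not None and pd.notna(pep) else None,
                proteins=proteins,
                search_db=str(row.get("search_db", search_db or "")),
                is_decoy=bool(int(row.get("is_decoy", 0) or 0)),
            )
        )
    return PSMSet(psms, search_db or (psms[0].search_db if psms else ""))


def write_psm_table(psms: PSMSet, path: str | Path) -> None:
    psms.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# confidence filtering

#: charge-dependent XCorr acceptance thresholds; the final bucket applies to
#: every charge above 7.
DEFAULT_XCORR_THRESHOLDS: dict[int | str, float] = {
    1: 1.5,
    2: 2.0,
    3: 2.25,
    4: 2.5,
    5: 2.75,
    6: 3.0,
    7: 3.2,
    "over7": 3.4,
}


@dataclass(frozen=True)
class FilterCriteria:
    """PSM- and protein-level confidence criteria.

    ``protein_score_min`` refers to the vendor's protein score when the
    input carries one; otherwise the sum of retained PSM XCorr per group is
    used as a documented proxy.
    """

    q_max: float = 0.01
    xcorr_min_by_charge: Mapping[int | str, float] = field(
        default_factory=lambda: dict(DEFAULT_XCORR_THRESHOLDS)
    )
    top_rank_only: bool = True
    min_unique_peptides_per_protein: int = 1
    protein_score_min: float = 10.0
    require_high_confidence: bool = False

    def __post_init__(self) -> None:
        for charge in list(range(1, 8)) + ["over7"]:
            if charge not in self.xcorr_min_by_charge:
                raise ValueError(f"xcorr_min_by_charge lacks bucket {charge!r}")
        if any(v < 0 for v in self.xcorr_min_by_charge.values()) or self.q_max < 0:
            raise ValueError("thresholds must be non-negative")

    def xcorr_threshold(self, charge: int) -> float:
        if charge < 1:
            raise ValueError(f"charge must be >= 1, got {charge}")
        return self.xcorr_min_by_charge[charge if charge <= 7 else "over7"]


def filter_psms(psms: PSMSet, criteria: FilterCriteria = FilterCriteria()) -> PSMSet:
    """Retain PSMs meeting the q-value, XCorr and rank criteria.

    A PSM is retained iff ``q <= q_max``, ``xcorr >= threshold(charge)``
    and (when ``top_rank_only``) ``rank == 1``.  Output order is stable.
    Protein-level criteria are applied after grouping by
    :func:`filter_protein_groups`, not here.
    """
    kept = []
    for p in psms:
        if p.q_value is None:
            raise MissingColumnError(
                f"scan {p.scan}: q_value required for filtering but absent"
            )
        if p.q_value > criteria.q_max:
            continue
        if p.xcorr < criteria.xcorr_threshold(p.charge):
            continue
        if criteria.top_rank_only and p.rank != 1:
            continue
        kept.append(p)
    return PSMSet(kept, psms.search_db)


# ---------------------------------------------------------------------------
# protein grouping (parsimony)


class GroupSpecies(str, Enum):
    HUMAN = "human"
    BOVINE = "bovine"
    UTILITY = "utility"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ProteinGroup:
    """Proteins indistinguishable by the observed peptides, reported as one.

    ``peptides`` is the set of peptide sequences *assigned* to this group
    by the parsimony procedure (each peptide is assigned to exactly one
    group); ``psm_count`` counts the PSMs carrying those peptides.
    """

    leader: str
    members: tuple[str, ...]
    peptides: frozenset[str]
    psm_count: int
    species: GroupSpecies | None = None


def _minimal_cover(
    candidates: list[tuple[tuple[str, ...], frozenset[str]]],
    universe: frozenset[str],
    exact_limit: int,
) -> list[int]:
    """Indices of a minimum-cardinality set cover of ``universe``.

    Exact search (increasing cover size, deterministic tie-break on the
    sorted leader tuple) up to ``exact_limit`` candidates; greedy beyond.
    """
    n = len(candidates)
    if n <= exact_limit:
        for r in range(1, n + 1):
            best: tuple[tuple[str, ...], tuple[int, ...]] | None = None
            for combo in itertools.combinations(range(n), r):
                covered = frozenset().union(*(candidates[i][1] for i in combo))
                if covered >= universe:
                    key = tuple(candidates[i][0][0] for i in combo)
                    if best is None or key < best[0]:
                        best = (key, combo)
            if best is not None:
                return list(best[1])
        return list(range(n))  # unreachable: all candidates cover the universe
    # greedy fallback for large components
    chosen: list[int] = []
    unexplained = set(universe)
    while unexplained:
        gain = [
            (len(candidates[i][1] & unexplained), len(candidates[i][1]), candidates[i][0][0], i)
            for i in range(n)
            if i not in chosen
        ]
        gain.sort(key=lambda t: (-t[0], -t[1], t[2]))
        if gain[0][0] == 0:
            break
        chosen.append(gain[0][3])
        unexplained -= candidates[gain[0][3]][1]
    return chosen


def group_proteins(
    psms: PSMSet | Iterable[PSM],
    species_of: Mapping[str, Species] | None = None,
    exact_limit: int = 14,
) -> list[ProteinGroup]:
    """Parsimonious protein grouping of (filtered) PSMs.

    Proteins with identical explained-peptide sets merge into one group;
    the reported groups form a minimum-cardinality set of protein groups
    explaining every observed peptide (exact minimal cover per connected
    component up to ``exact_limit`` candidate groups, greedy beyond).
    Each peptide is assigned to exactly one selected group -- the one with
    the most peptide evidence, ties broken by the lexicographically
    smallest leader accession.  Decoy PSMs are ignored.

    When ``species_of`` is given each group is annotated with its species
    (``ambiguous`` when member accessions span species).
    """
    pep_to_prots: dict[str, set[str]] = {}
    pep_psm_count: dict[str, int] = {}
    for p in psms:
        if p.is_decoy:
            continue
        pep_to_prots.setdefault(p.peptide, set()).update(p.proteins)
        pep_psm_count[p.peptide] = pep_psm_count.get(p.peptide, 0) + 1
    prot_to_peps: dict[str, set[str]] = {}
    for pep, prots in pep_to_prots.items():
        for prot in prots:
            prot_to_peps.setdefault(prot, set()).add(pep)

    # merge proteins with identical peptide evidence
    by_pepset: dict[frozenset[str], list[str]] = {}
    for prot, peps in prot_to_peps.items():
        by_pepset.setdefault(frozenset(peps), []).append(prot)
    candidates: list[tuple[tuple[str, ...], frozenset[str]]] = [
        (tuple(sorted(members)), pepset) for pepset, members in by_pepset.items()
    ]
    candidates.sort(key=lambda c: c[0][0])

    # connected components over shared peptides
    parent: dict[int, int] = {i: i for i in range(len(candidates))}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pep_owner: dict[str, int] = {}
    for i, (_, pepset) in enumerate(candidates):
        for pep in pepset:
            if pep in pep_owner:
                ri, rj = find(i), find(pep_owner[pep])
                if ri != rj:
                    parent[ri] = rj
            else:
                pep_owner[pep] = i
    comps: dict[int, list[int]] = {}
    for i in range(len(candidates)):
        comps.setdefault(find(i), []).append(i)

    selected: list[int] = []
    for comp in comps.values():
        sub = [candidates[i] for i in comp]
        universe = frozenset().union(*(c[1] for c in sub)) if sub else frozenset()
        chosen_local = _minimal_cover(sub, universe, exact_limit)
        selected.extend(comp[i] for i in chosen_local)

    # assign each peptide to exactly one selected group
    claims: dict[int, set[str]] = {i: set() for i in selected}
    for pep in pep_to_prots:
        owners = [i for i in selected if pep in candidates[i][1]]
        owners.sort(key=lambda i: (-len(candidates[i][1]), candidates[i][0][0]))
        claims[owners[0]].add(pep)

    groups: list[ProteinGroup] = []
    for i in sorted(selected, key=lambda i: candidates[i][0][0]):
        members, _ = candidates[i]
        claimed = frozenset(claims[i])
        if not claimed:
            continue
        species: GroupSpecies | None = None
        if species_of is not None:
            kinds = {species_of[m].value for m in members if m in species_of}
            species = (
                GroupSpecies(kinds.pop()) if len(kinds) == 1 else GroupSpecies.AMBIGUOUS
            )
        groups.append(
            ProteinGroup(
                leader=members[0],
                members=members,
                peptides=claimed,
                psm_count=sum(pep_psm_count[p] for p in claimed),
                species=species,
            )
        )
    return groups


def filter_protein_groups(
    groups: Sequence[ProteinGroup],
    psms: PSMSet,
    criteria: FilterCriteria = FilterCriteria(),
) -> list[ProteinGroup]:
    """Apply the protein-level criteria after grouping.

    A group is retained iff it has at least
    ``min_unique_peptides_per_protein`` peptides and its score (sum of its
    PSMs' XCorr, a proxy for the vendor protein score) reaches
    ``protein_score_min``.
    """
    out = []
    for g in groups:
        if len(g.peptides) < criteria.min_unique_peptides_per_protein:
            continue
        score = sum(p.xcorr for p in psms if not p.is_decoy and p.peptide in g.peptides)
        if score < criteria.protein_score_min:
            continue
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# target-decoy q-values


def estimate_q_values(psms: PSMSet) -> PSMSet:
    """Fill q-values by target-decoy counting on the XCorr score.

    At each score threshold t, ``FDR(t) = #decoys(score >= t) /
    #targets(score >= t)``; the q-value of a PSM is the minimum FDR over
    thresholds at or below its score, so q is non-increasing in score.
    Raises :class:`NoDecoysError` when the set contains no decoys.
    """
    if not any(p.is_decoy for p in psms):
        raise NoDecoysError("q-value estimation requires decoy PSMs")
    order = sorted(range(len(psms)), key=lambda i: -psms[i].xcorr)
    n_decoys = 0
    n_targets = 0
    fdr = [0.0] * len(psms)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and psms[order[j]].xcorr == psms[order[i]].xcorr:
            if psms[order[j]].is_decoy:
                n_decoys += 1
            else:
                n_targets += 1
            j += 1
        value = min(1.0, n_decoys / max(n_targets, 1))
        for k in range(i, j):
            fdr[order[k]] = value
        i = j
    # monotonize: q(score) = min FDR at or below that score
    q = list(fdr)
    running = 1.0
    for idx in reversed(order):
        running = min(running, fdr[idx])
        q[idx] = running
    return PSMSet(
        [replace(p, q_value=q[i]) for i, p in enumerate(psms)], psms.search_db
    )
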