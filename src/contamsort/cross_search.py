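"""Comparing one MS/MS dataset searched against multiple databases.

Two analyses diagnose how a search database shapes secretome results:

* a **species census** of PSMs and protein groups -- each PSM is classed as
  human, major-FBS contaminant, minor-FBS contaminant, other bovine,
  orthologous (its peptide occurs in both species, so neither can be
  claimed) or utility; the classes partition the PSM set;
* a **per-spectrum score comparison** between two searches of the same
  spectra -- for each spectrum the difference of -log10 posterior error
  probabilities, ``delta = (-logPEP)_B - (-logPEP)_A``, assigns a region:
  ``grey`` (|delta| below the threshold: both searches agree), ``red``
  (search B markedly more confident), ``green`` (search A markedly more
  confident), ``blue`` (matched in B only), plus ``a_only_unmatched`` for
  spectra matched in A only.

A human-only search of a contaminated secretome pushes bovine-unique
spectra into the blue region (no sequence to match) or the red region
(false-positive human match beaten by the contaminant sequence once it is
in the database); those regions are the operational signature of FBS
contamination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .digestion_index import PeptideClass, PeptideIndex, classify_peptide
from .errors import DatabaseMismatchError, MissingColumnError
from .psm_pipeline import PSM, PSMSet, GroupSpecies, ProteinGroup
from .sequence_db import Species


class PsmClass(str, Enum):
    HUMAN = "human"
    MAJOR_FBS = "major_fbs"
    MINOR_FBS = "minor_fbs"
    OTHER_BOVINE = "other_bovine"
    ORTHOLOGOUS = "orthologous"
    UTILITY = "utility"


@dataclass(frozen=True)
class ContaminantLists:
    """FBS contaminant accessions split into major and minor lists.

    ``major_fbs`` holds the dominant contaminants (the most abundant
    serum proteins plus those recovered from residual serum in media and
    on plate surfaces); ``minor_fbs`` holds the remaining profiled FBS
    proteins.  The two are disjoint.
    """

    major_fbs: frozenset[str]
    minor_fbs: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.major_fbs & self.minor_fbs
        if overlap:
            raise ValueError(f"major/minor lists overlap: {sorted(overlap)[:5]}")

    @property
    def all_fbs(self) -> frozenset[str]:
        return self.major_fbs | self.minor_fbs


@dataclass(frozen=True)
class SpeciesCensus:
    """Per-class PSM counts; classes partition the census'd set."""

    counts: Mapping[PsmClass, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("census classes must partition the PSM set")

    def fraction(self, cls: PsmClass) -> float:
        return self.counts.get(cls, 0) / self.total if self.total else 0.0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "counts": {c.value: n for c, n in self.counts.items()},
            "fractions": {c.value: self.fraction(c) for c in self.counts},
        }


def classify_psm(
    psm: PSM,
    index: PeptideIndex,
    lists: ContaminantLists,
    species_of: Mapping[str, Species],
) -> PsmClass:
    """Species class of one PSM.

    Orthologous whenever the peptide itself is shared between species
    (regardless of the reported protein); utility when only utility
    proteins produce it; otherwise by the species and contaminant-list
    membership of the PSM's assigned protein.
    """
    pep_class = classify_peptide(psm.peptide, index)
    if pep_class is PeptideClass.SHARED:
        return PsmClass.ORTHOLOGOUS
    if pep_class is PeptideClass.UTILITY_ONLY:
        return PsmClass.UTILITY
    for acc in psm.proteins:
        if acc in species_of:
            species = species_of[acc]
            break
    else:
        raise DatabaseMismatchError(
            f"scan {psm.scan}: proteins {psm.proteins} absent from the "
            "index's databases"
        )
    if species is Species.UTILITY:
        return PsmClass.UTILITY
    if species is Species.BOVINE:
        if acc in lists.major_fbs:
            return PsmClass.MAJOR_FBS
        if acc in lists.minor_fbs:
            return PsmClass.MINOR_FBS
        return PsmClass.OTHER_BOVINE
    return PsmClass.HUMAN


def census_psms(
    psms: PSMSet | Iterable[PSM],
    index: PeptideIndex,
    lists: ContaminantLists,
    species_of: Mapping[str, Species],
) -> SpeciesCensus:
    """Census of PSM species classes (decoy PSMs are excluded)."""
    counts: dict[PsmClass, int] = {c: 0 for c in PsmClass}
    total = 0
    for psm in psms:
        if psm.is_decoy:
            continue
        counts[classify_psm(psm, index, lists, species_of)] += 1
        total += 1
    return SpeciesCensus(counts, total)


def psm_classes(
    psms: PSMSet | Iterable[PSM],
    index: PeptideIndex,
    lists: ContaminantLists,
    species_of: Mapping[str, Species],
) -> list[PsmClass]:
    """Per-PSM class labels aligned with the (non-decoy) input order."""
    return [
        classify_psm(p, index, lists, species_of) for p in psms if not p.is_decoy
    ]


def census_protein_groups(
    groups: Sequence[ProteinGroup],
    lists: ContaminantLists,
) -> dict[str, int]:
    """Group counts per class, by each group's leader species/list membership.

    Mixed-species groups are reported separately as ``ambiguous``.
    """
    counts = {c.value: 0 for c in PsmClass if c is not PsmClass.ORTHOLOGOUS}
    counts["ambiguous"] = 0
    for g in groups:
        if g.species is None:
            raise ValueError(
                f"group {g.leader}: species annotation required for the census"
            )
        if g.species is GroupSpecies.AMBIGUOUS:
            counts["ambiguous"] += 1
        elif g.species is GroupSpecies.UTILITY:
            counts[PsmClass.UTILITY.value] += 1
        elif g.species is GroupSpecies.BOVINE:
            if g.leader in lists.major_fbs:
                counts[PsmClass.MAJOR_FBS.value] += 1
            elif g.leader in lists.minor_fbs:
                counts[PsmClass.MINOR_FBS.value] += 1
            else:
                counts[PsmClass.OTHER_BOVINE.value] += 1
        else:
            counts[PsmClass.HUMAN.value] += 1
    return counts


@dataclass(frozen=True)
class VennResult:
    """Human protein-group leaders partitioned across two searches."""

    label_a: str
    label_b: str
    only_in_a: frozenset[str]
    only_in_b: frozenset[str]
    both: frozenset[str]


def venn_human_proteins(
    groups_by_db: Mapping[str, Sequence[ProteinGroup]],
) -> VennResult:
    """Partition human protein-group leaders by presence across two searches."""
    if len(groups_by_db) != 2:
        raise ValueError("venn_human_proteins expects exactly two search results")
    (label_a, groups_a), (label_b, groups_b) = groups_by_db.items()

    def human_leaders(groups: Sequence[ProteinGroup]) -> frozenset[str]:
        return frozenset(
            g.leader for g in groups if g.species is GroupSpecies.HUMAN
        )

    a, b = human_leaders(groups_a), human_leaders(groups_b)
    return VennResult(label_a, label_b, a - b, b - a, a & b)


# ---------------------------------------------------------------------------
# per-spectrum cross-database comparison


class Region(str, Enum):
    GREY = "grey"
    BLUE = "blue"
    RED = "red"
    GREEN = "green"
    A_ONLY_UNMATCHED = "a_only_unmatched"


@dataclass(frozen=True)
class ComparisonRecord:
    spectrum_key: tuple[str, int]
    neglogpep_a: float | None
    neglogpep_b: float | None
    delta: float | None
    region: Region
    species_a: PsmClass | None = None
    species_b: PsmClass | None = None

    @property
    def species_switch(self) -> tuple[PsmClass, PsmClass] | None:
        if (
            self.species_a is not None
            and self.species_b is not None
            and self.species_a is not self.species_b
        ):
            return (self.species_a, self.species_b)
        return None


def neg_log_pep(pep: float, floor: float = 1e-10) -> float:
    """-log10(PEP), with PEP floored at ``floor`` to avoid infinities."""
    return -math.log10(max(pep, floor))


def _best_by_spectrum(psms: PSMSet | Iterable[PSM]) -> dict[tuple[str, int], PSM]:
    """Best (lowest-PEP) PSM per spectrum key; duplicates at identical
    (file, scan, charge) are an error."""
    best: dict[tuple[str, int], PSM] = {}
    seen_full: set[tuple[str, int, int]] = set()
    for p in psms:
        if p.is_decoy:
            continue
        if p.pep is None:
            raise MissingColumnError(
                f"scan {p.scan}: PEP required for cross-search comparison"
            )
        full = (p.spectrum_file, p.scan, p.charge)
        if full in seen_full:
            raise ValueError(f"duplicate spectrum {full} within one search result")
        seen_full.add(full)
        cur = best.get(p.spectrum_key)
        if cur is None or p.pep < cur.pep:
            best[p.spectrum_key] = p
    return best


def compare_searches(
    psms_a: PSMSet,
    psms_b: PSMSet,
    delta_threshold: float = 0.7,
    pep_floor: float = 1e-10,
    classifier: Callable[[PSM], PsmClass] | None = None,
) -> list[ComparisonRecord]:
    """Join two search results on spectrum key and assign score regions.

    ``delta = (-log10 PEP_b) - (-log10 PEP_a)``; regions follow the sign
    and magnitude of delta (a delta of exactly +/- the threshold counts as
    red/green).  ``classifier`` (PSM -> species class) fills the
    per-search species labels so cross-database species switches can be
    read off the records.
    """
    best_a = _best_by_spectrum(psms_a)
    best_b = _best_by_spectrum(psms_b)
    records: list[ComparisonRecord] = []
    for key in sorted(set(best_a) | set(best_b)):
        pa, pb = best_a.get(key), best_b.get(key)
        nla = neg_log_pep(pa.pep, pep_floor) if pa is not None else None
        nlb = neg_log_pep(pb.pep, pep_floor) if pb is not None else None
        sa = classifier(pa) if classifier is not None and pa is not None else None
        sb = classifier(pb) if classifier is not None and pb is not None else None
        if pa is None:
            region, delta = Region.BLUE, None
        elif pb is None:
            region, delta = Region.A_ONLY_UNMATCHED, None
        else:
            delta = nlb - nla
            if delta >= delta_threshold:
                region = Region.RED
            elif delta <= -delta_threshold:
                region = Region.GREEN
            else:
                region = Region.GREY
        records.append(ComparisonRecord(key, nla, nlb, delta, region, sa, sb))
    return records


def region_counts(records: Sequence[ComparisonRecord]) -> dict[str, int]:
    counts = {r.value: 0 for r in Region}
    for rec in records:
        counts[rec.region.value] += 1
    return counts


def comparison_to_dataframe(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spectrum_file": [r.spectrum_key[0] for r in records],
            "scan": [r.spectrum_key[1] for r in records],
            "neglogpep_a": [r.neglogpep_a for r in records],
            "neglogpep_b": [r.neglogpep_b for r in records],
            "delta": [r.delta for r in records],
            "region": [r.region.value for r in records],
            "species_a": [r.species_a.value if r.species_a else None for r in records],
            "species_b": [r.species_b.value if r.species_b else None for r in records],
        }
    )


_REGION_COLORS = {
    Region.GREY: "0.6",
    Region.BLUE: "tab:blue",
    Region.RED: "tab:red",
    Region.GREEN: "tab:green",
    Region.A_ONLY_UNMATCHED: "tab:orange",
}


def plot_pep_comparison(
    records: Sequence[ComparisonRecord],
    path=None,
    ax=None,
    label_a: str = "search A",
    label_b: str = "search B",
):
    """Scatter of -logPEP pairs coloured by region (spectra missing on one
    side are drawn on the corresponding axis at 0)."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for region in Region:
        xs = [r.neglogpep_a or 0.0 for r in records if r.region is region]
        ys = [r.neglogpep_b or 0.0 for r in records if r.region is region]
        if xs:
            ax.scatter(xs, ys, s=4, c=_REGION_COLORS[region], label=region.value)
    ax.set_xlabel(f"-log10 PEP ({label_a})")
    ax.set_ylabel(f"-log10 PEP ({label_b})")
    ax.legend(markerscale=3, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
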