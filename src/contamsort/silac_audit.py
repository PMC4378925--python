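"""SILAC label auditing of search results.

In SILAC (stable isotope labeling by amino acids in cell culture) only
proteins newly synthesised by the cultured cells incorporate heavy
arginine (Arg10, +10.01 Da) and lysine (Lys8, +8.01 Da); serum proteins
carried over from the medium stay unlabeled, and metabolic Arg->Pro
conversion adds a +6.01 Da heavy proline at a low rate.  Counting labeled
versus unlabeled R/K/P residues per species class therefore provides an
orthogonal, experiment-based check on whether PSMs attributed to bovine
contaminants are genuine: true contaminants must be unlabeled, while a
"bovine" protein supported by isotope-labeled peptides is almost certainly
a false positive from the cells' own proteome.

The audit has two levels: a per-residue census (labeled/unlabeled counts
for R, K and P per species class) and a per-protein classification
(labeled / partially labeled / non-labeled from the label states of each
group's peptides).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .cross_search import PsmClass
from .errors import LabelMismatchError
from .modifications import DEFAULT_SPECS, ModificationSpec
from .psm_pipeline import PSM, PSMSet, ProteinGroup

RESIDUES = ("R", "K", "P")


@dataclass(frozen=True)
class ResidueFlag:
    """Label state of one R/K/P residue in a peptide."""

    position: int
    residue: str
    labeled: bool


def annotate_labels(
    psm: PSM, specs: Sequence[ModificationSpec] = DEFAULT_SPECS
) -> list[ResidueFlag]:
    """Label flags for every R/K/P residue of the PSM's peptide.

    A residue is labeled iff a modification whose spec ``is_label`` sits at
    its position and targets its residue type.  A label modification on a
    non-matching residue indicates a corrupt table and raises
    :class:`LabelMismatchError`.
    """
    by_name = {s.name: s for s in specs}
    labeled_positions: set[int] = set()
    for mod in psm.modifications:
        spec = by_name.get(mod.name)
        if spec is None or not spec.is_label or mod.position is None:
            continue
        if psm.peptide[mod.position] != spec.residue:
            raise LabelMismatchError(
                f"scan {psm.scan}: label {mod.name} at position {mod.position} "
                f"sits on {psm.peptide[mod.position]!r}, expected {spec.residue!r}"
            )
        labeled_positions.add(mod.position)
    return [
        ResidueFlag(i, aa, i in labeled_positions)
        for i, aa in enumerate(psm.peptide)
        if aa in RESIDUES
    ]


def is_labeled_psm(psm: PSM, specs: Sequence[ModificationSpec] = DEFAULT_SPECS) -> bool:
    """A PSM is labeled iff it carries at least one label modification."""
    return any(flag.labeled for flag in annotate_labels(psm, specs))


class SilacResidueCensus:
    """Labeled/unlabeled counts per (species class, residue type)."""

    def __init__(self) -> None:
        self._counts: dict[str, dict[str, list[int]]] = {}

    def add(self, cls: str, residue: str, labeled: bool) -> None:
        per_res = self._counts.setdefault(cls, {r: [0, 0] for r in RESIDUES})
        per_res[residue][0 if labeled else 1] += 1

    def classes(self) -> list[str]:
        return sorted(self._counts)

    def counts(self, cls: str, residue: str) -> tuple[int, int]:
        """(labeled, unlabeled) count for one class and residue type."""
        pair = self._counts.get(cls, {}).get(residue, [0, 0])
        return (pair[0], pair[1])

    def total(self, cls: str, residue: str) -> int:
        labeled, unlabeled = self.counts(cls, residue)
        return labeled + unlabeled

    def labeled_fraction(self, cls: str, residue: str) -> float:
        labeled, unlabeled = self.counts(cls, residue)
        n = labeled + unlabeled
        return labeled / n if n else 0.0

    def to_dict(self) -> dict:
        return {
            cls: {
                res: {
                    "labeled": self.counts(cls, res)[0],
                    "unlabeled": self.counts(cls, res)[1],
                    "labeled_fraction": self.labeled_fraction(cls, res),
                }
                for res in RESIDUES
            }
            for cls in self.classes()
        }


def residue_census(
    psms: PSMSet | Iterable[PSM],
    classes: Sequence[PsmClass | str],
    specs: Sequence[ModificationSpec] = DEFAULT_SPECS,
) -> SilacResidueCensus:
    """Count labeled/unlabeled R/K/P residues per species class.

    ``classes`` carries the per-PSM species class labels aligned with the
    (non-decoy) PSMs, as produced by :func:`contamsort.cross_search.psm_classes`.
    """
    psm_list = [p for p in psms if not p.is_decoy]
    if len(psm_list) != len(classes):
        raise ValueError(
            f"{len(classes)} class labels for {len(psm_list)} non-decoy PSMs"
        )
    census = SilacResidueCensus()
    for psm, cls in zip(psm_list, classes):
        cls_value = cls.value if isinstance(cls, PsmClass) else str(cls)
        for flag in annotate_labels(psm, specs):
            census.add(cls_value, flag.residue, flag.labeled)
    return census


class LabelStatus(str, Enum):
    LABELED = "labeled"
    PARTIALLY_LABELED = "partially_labeled"
    NON_LABELED = "non_labeled"


@dataclass(frozen=True)
class ProteinLabelStatus:
    group: ProteinGroup
    status: LabelStatus
    n_labeled: int
    n_unlabeled: int


def classify_protein_labels(
    groups: Sequence[ProteinGroup],
    psms: PSMSet | Iterable[PSM],
    specs: Sequence[ModificationSpec] = DEFAULT_SPECS,
    level: str = "observation",
    classes: Sequence[PsmClass | str] | None = None,
) -> list[ProteinLabelStatus]:
    """Classify each protein group as labeled / partially labeled / non-labeled.

    A group is *labeled* when every supporting peptide is labeled,
    *non-labeled* when none is, *partially labeled* otherwise.

    ``level`` chooses the peptide unit: ``"observation"`` (default)
    aggregates PSMs by (sequence, charge) and counts a peptide observed in
    both labeled and unlabeled form as two observations; ``"peptide"``
    collapses to the bare sequence, labeled iff any supporting PSM carries
    a label.

    When per-PSM species ``classes`` are supplied, PSMs of orthologous
    (species-shared) peptides are excluded from the evidence: a peptide
    that both species can produce cannot testify about the labeling of one
    species' protein.  Groups whose every PSM is orthologous fall back to
    the full evidence.  Raises for groups with no supporting PSMs at all.
    """
    if level not in ("observation", "peptide"):
        raise ValueError(f"unknown level {level!r}")
    psm_list = [p for p in psms if not p.is_decoy]
    if classes is not None and len(classes) != len(psm_list):
        raise ValueError(
            f"{len(classes)} class labels for {len(psm_list)} non-decoy PSMs"
        )

    def tally(group: ProteinGroup, include_shared: bool) -> tuple[int, int]:
        units: dict[tuple, set[bool]] = {}
        for i, p in enumerate(psm_list):
            if p.peptide not in group.peptides:
                continue
            if not include_shared and classes is not None:
                cls = classes[i]
                cls_value = cls.value if isinstance(cls, PsmClass) else str(cls)
                if cls_value == PsmClass.ORTHOLOGOUS.value:
                    continue
            key = (p.peptide, p.charge) if level == "observation" else (p.peptide,)
            units.setdefault(key, set()).add(is_labeled_psm(p, specs))
        if level == "observation":
            n_labeled = sum(True in states for states in units.values())
            n_unlabeled = sum(False in states for states in units.values())
        else:
            n_labeled = sum(1 for states in units.values() if True in states)
            n_unlabeled = sum(1 for states in units.values() if True not in states)
        return n_labeled, n_unlabeled

    out: list[ProteinLabelStatus] = []
    for group in groups:
        n_labeled, n_unlabeled = tally(group, include_shared=classes is None)
        if n_labeled + n_unlabeled == 0:
            n_labeled, n_unlabeled = tally(group, include_shared=True)
        if n_labeled + n_unlabeled == 0:
            raise ValueError(f"group {group.leader}: no supporting PSMs")
        if n_unlabeled == 0:
            status = LabelStatus.LABELED
        elif n_labeled == 0:
            status = LabelStatus.NON_LABELED
        else:
            status = LabelStatus.PARTIALLY_LABELED
        out.append(ProteinLabelStatus(group, status, n_labeled, n_unlabeled))
    return out


def silac_report(
    psms: PSMSet,
    groups: Sequence[ProteinGroup],
    classes: Sequence[PsmClass | str],
    specs: Sequence[ModificationSpec] = DEFAULT_SPECS,
) -> dict:
    """Full audit: residue census per class plus protein status counts.

    Protein status counts are reported per group species and at both
    peptide-unit levels (observation and bare sequence).
    """
    census = residue_census(psms, classes, specs)
    report: dict = {"residue_census": census.to_dict(), "protein_status": {}}
    for level in ("observation", "peptide"):
        statuses = classify_protein_labels(
            groups, psms, specs, level=level, classes=classes
        )
        by_species: dict[str, dict[str, int]] = {}
        for st in statuses:
            species = st.group.species.value if st.group.species else "unknown"
            bucket = by_species.setdefault(
                species, {s.value: 0 for s in LabelStatus}
            )
            bucket[st.status.value] += 1
        report["protein_status"][level] = by_species
    return report
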