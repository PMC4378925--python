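"""Synthetic proteomes, PSM tables and SILAC annotations with ground truth.

The generator emulates the structure of a contaminated secretome
experiment end to end so every pipeline stage can be exercised against a
known answer:

* a human proteome and a bovine proteome in which a controlled fraction of
  bovine proteins are *orthologous clones* of human proteins -- each clone
  preserves exactly one tryptic peptide of its human source and substitutes
  every residue outside it (K<->R swapped, P fixed, so the tryptic cleavage
  pattern is preserved), giving exact control over the set of
  species-shared peptides;
* an FBS contaminant list drawn from the bovine proteome with Zipf-like
  abundances (so the top of the list dominates contaminant PSMs, as the
  most abundant serum proteins do), split into major/minor sublists;
* per-database PSM tables for one set of spectra "searched" against a
  human-only, a human+FBS and a human+bovine database: a spectrum yields a
  PSM only when the database contains a parent of its peptide, incorrect
  low-score matches appear at a configurable rate, XCorr is drawn from
  separated correct/incorrect score distributions, PEP is a logistic
  function of XCorr, and q-values come from generated decoys by
  target-decoy counting;
* optional SILAC annotations: cell-derived (human-origin) PSMs receive
  heavy Arg/Lys at the configured incorporation efficiency (plus heavy Pro
  at a low Arg->Pro conversion rate), serum-derived PSMs stay unlabeled.

All randomness flows through seeded NumPy generators; identical seed and
configuration give identical output.  The score model is a test harness,
not a claim about any instrument.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cross_search import ContaminantLists
from .digestion_index import DigestionParams, PeptideIndex, build_index, digest
from .modifications import Modification, SPEC_BY_NAME
from .psm_pipeline import PSM, PSMSet, estimate_q_values, write_psm_table
from .sequence_db import (
    ProteinRecord,
    SequenceDatabase,
    Species,
    build_fbs_database,
    write_fasta,
)

#: database content labels understood by the table generator
DB_CONTENTS = ("human", "human+fbs", "human+bovine")
DEFAULT_DATABASES: dict[str, str] = {
    "HuDB": "human",
    "HFDB": "human+fbs",
    "HBDB": "human+bovine",
}

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# K/R boosted to ~11% combined so tryptic peptides have realistic lengths
_AA_PROBS = np.full(20, (1.0 - 0.055 * 2 - 0.05) / 17)
_AA_PROBS[np.where(_AA == "K")[0][0]] = 0.055
_AA_PROBS[np.where(_AA == "R")[0][0]] = 0.055
_AA_PROBS[np.where(_AA == "P")[0][0]] = 0.05

# residue substitution preserving the tryptic cleavage pattern:
# K<->R, P fixed, the 17 remaining letters cycled
_NON_KRP = "ACDEFGHILMNQSTVWY"
_SIGMA = {a: _NON_KRP[(i + 1) % len(_NON_KRP)] for i, a in enumerate(_NON_KRP)}
_SIGMA.update({"K": "R", "R": "K", "P": "P"})


@dataclass(frozen=True)
class ScoreModel:
    """Score distributions for correct and incorrect PSMs.

    XCorr is Gaussian per class; PEP is a logistic function of XCorr,
    ``PEP = 1 / (1 + exp(slope * (xcorr - midpoint)))``, with a small
    per-database jitter on XCorr so re-searches of the same spectrum do
    not score identically.
    """

    xcorr_correct_mean: float = 3.5
    xcorr_correct_sd: float = 0.5
    xcorr_incorrect_mean: float = 1.5
    xcorr_incorrect_sd: float = 0.4
    pep_slope: float = 3.0
    pep_midpoint: float = 2.3
    db_noise_sd: float = 0.05

    def pep_from_xcorr(self, xcorr: float) -> float:
        pep = 1.0 / (1.0 + float(np.exp(self.pep_slope * (xcorr - self.pep_midpoint))))
        return float(min(max(pep, 1e-12), 1.0))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic experiment.

    Defaults encode the conditions the contaminated-secretome setting
    implies: a contaminant PSM fraction of 7% (the middle of the expected
    5--10% range for serum carry-over), a 30-protein major-contaminant
    list dominating the serum by abundance, and >95% SILAC incorporation
    (97% by default).
    """

    seed: int = 0
    n_human_proteins: int = 200
    n_bovine_proteins: int = 80
    n_fbs_proteins: int = 40
    protein_length: tuple[int, int] = (120, 360)
    orthology_fraction: float = 0.25
    n_spectra: int = 1000
    contaminant_psm_fraction: float = 0.07
    major_fbs_count: int = 30
    label_efficiency: float = 0.97
    pro_conversion_rate: float = 0.03
    incorrect_psm_rate: float = 0.05
    score_model: ScoreModel = field(default_factory=ScoreModel)
    digestion: DigestionParams = field(default_factory=DigestionParams)

    def __post_init__(self) -> None:
        for name in (
            "orthology_fraction",
            "contaminant_psm_fraction",
            "label_efficiency",
            "pro_conversion_rate",
            "incorrect_psm_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")
        if self.n_fbs_proteins > self.n_bovine_proteins:
            raise ValueError("n_fbs_proteins cannot exceed n_bovine_proteins")
        if not (0 < self.protein_length[0] <= self.protein_length[1]):
            raise ValueError("invalid protein_length range")


@dataclass
class SpectrumTruth:
    """Ground truth for one spectrum across all databases."""

    scan: int
    origin: str  # "human" (cell-derived) or "fbs" (serum contaminant)
    source_accession: str
    peptide: str
    in_human: bool
    in_fbs: bool
    in_bovine: bool
    per_db: dict[str, str] = field(default_factory=dict)  # correct|incorrect|absent


@dataclass
class GroundTruth:
    """Complete generator bookkeeping for one synthetic experiment."""

    species: dict[str, str] = field(default_factory=dict)
    major_fbs: list[str] = field(default_factory=list)
    minor_fbs: list[str] = field(default_factory=list)
    fbs_weights: dict[str, float] = field(default_factory=dict)
    shared_peptides: list[str] = field(default_factory=list)
    ortho_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    spectra: dict[int, SpectrumTruth] = field(default_factory=dict)
    #: search_db -> scan -> [(position, residue, labeled), ...]
    label_truth: dict[str, dict[int, list[tuple[int, str, bool]]]] = field(
        default_factory=dict
    )

    def contaminant_scans(self) -> list[int]:
        return [s.scan for s in self.spectra.values() if s.origin == "fbs"]

    def bovine_unique_contaminant_scans(self) -> list[int]:
        """Contaminant spectra whose peptide no human protein can produce."""
        return [
            s.scan
            for s in self.spectra.values()
            if s.origin == "fbs" and not s.in_human
        ]

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "major_fbs": self.major_fbs,
            "minor_fbs": self.minor_fbs,
            "shared_peptides": self.shared_peptides,
            "ortho_pairs": [list(t) for t in self.ortho_pairs],
            "spectra": {
                str(scan): {
                    "origin": s.origin,
                    "source_accession": s.source_accession,
                    "peptide": s.peptide,
                    "in_human": s.in_human,
                    "in_fbs": s.in_fbs,
                    "in_bovine": s.in_bovine,
                    "per_db": s.per_db,
                }
                for scan, s in sorted(self.spectra.items())
            },
            "label_truth": {
                db: {
                    str(scan): [[p, r, bool(l)] for p, r, l in flags]
                    for scan, flags in sorted(per_db.items())
                }
                for db, per_db in self.label_truth.items()
            },
        }


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_PROBS))


def _clone_with_preserved_peptide(
    source: str, rng: np.random.Generator, params: DigestionParams
) -> tuple[str, str] | None:
    """Clone ``source`` preserving one tryptic peptide, mutating the rest.

    Returns (clone sequence, preserved peptide) or None when the source has
    no fully-tryptic zero-missed-cleavage peptide within the length bounds.
    """
    candidates = digest(source, replace(params, max_missed_cleavages=0))
    if not candidates:
        return None
    pick = candidates[int(rng.integers(len(candidates)))]
    clone = "".join(
        source[i] if pick.start <= i < pick.end else _SIGMA[source[i]]
        for i in range(len(source))
    )
    return clone, pick.sequence


def generate_proteomes(
    config: SyntheticConfig,
) -> tuple[SequenceDatabase, SequenceDatabase, ContaminantLists, GroundTruth]:
    """Generate paired human/bovine proteomes and the FBS contaminant lists.

    A fraction ``orthology_fraction`` of bovine proteins are clones of
    distinct human proteins sharing exactly one tryptic peptide each; the
    FBS list (``n_fbs_proteins`` bovine accessions) gets Zipf abundance
    weights and is split into major (top ``major_fbs_count`` by weight)
    and minor sublists.  Raises when the proteomes are too small to
    realise the requested orthology.
    """
    rng = np.random.default_rng([config.seed, 101])
    truth = GroundTruth()
    lo, hi = config.protein_length

    human_records = []
    for i in range(config.n_human_proteins):
        acc = f"HUM{i:04d}"
        seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        human_records.append(
            ProteinRecord(acc, f"synthetic human protein {i}", Species.HUMAN, seq, "HuDB")
        )
        truth.species[acc] = "human"
    human_db = SequenceDatabase("HuDB", human_records)

    n_ortho = int(round(config.orthology_fraction * config.n_bovine_proteins))
    if n_ortho > config.n_human_proteins:
        raise ValueError(
            "orthology_fraction requires more human source proteins than available"
        )
    bovine_records = []
    shared: set[str] = set()
    for i in range(config.n_bovine_proteins):
        acc = f"BOV{i:04d}"
        if i < n_ortho:
            source = human_records[i]
            result = _clone_with_preserved_peptide(
                source.sequence, rng, config.digestion
            )
            if result is None:
                raise ValueError(
                    f"human source {source.accession} yields no tryptic peptide "
                    "within the length bounds; increase protein_length"
                )
            seq, preserved = result
            shared.add(config.digestion.canonical(preserved))
            truth.ortho_pairs.append((source.accession, acc, preserved))
            desc = f"synthetic bovine ortholog of {source.accession}"
        else:
            seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
            desc = f"synthetic bovine protein {i}"
        bovine_records.append(ProteinRecord(acc, desc, Species.BOVINE, seq, "BoDB"))
        truth.species[acc] = "bovine"
    bovine_db = SequenceDatabase("BoDB", bovine_records)
    if config.orthology_fraction > 0 and not shared:
        raise ValueError("proteomes too small to realise any shared peptide")
    truth.shared_peptides = sorted(shared)

    # FBS list: ortho clones are eligible alongside random bovine proteins;
    # Zipf weights over a random permutation set the abundance ranking.
    fbs_pool = [r.accession for r in bovine_records]
    fbs_accs = list(rng.permutation(fbs_pool)[: config.n_fbs_proteins])
    weights = np.array([1.0 / (r + 1) for r in range(len(fbs_accs))])
    weights /= weights.sum()
    n_major = min(config.major_fbs_count, len(fbs_accs))
    truth.major_fbs = list(fbs_accs[:n_major])
    truth.minor_fbs = list(fbs_accs[n_major:])
    truth.fbs_weights = {acc: float(w) for acc, w in zip(fbs_accs, weights)}
    lists = ContaminantLists(
        frozenset(truth.major_fbs), frozenset(truth.minor_fbs)
    )
    return human_db, bovine_db, lists, truth


def _unique_peptides(db: SequenceDatabase, params: DigestionParams) -> dict[str, list[str]]:
    return {
        rec.accession: sorted({p.sequence for p in digest(rec.sequence, params)})
        for rec in db
    }


def generate_psm_tables(
    config: SyntheticConfig,
    human_db: SequenceDatabase,
    bovine_db: SequenceDatabase,
    lists: ContaminantLists,
    truth: GroundTruth,
    databases: Mapping[str, str] | None = None,
) -> dict[str, PSMSet]:
    """Emit one PSM table per search database for a shared set of spectra.

    Every spectrum carries a true peptide sampled from a human protein
    (probability ``1 - contaminant_psm_fraction``) or from an FBS protein
    (abundance-weighted).  Per database the spectrum yields a correct PSM
    when the database contains a parent of the peptide, an incorrect
    low-score PSM with probability ``incorrect_psm_rate``, and no PSM
    otherwise.  Each table includes an equal number of decoy PSMs and has
    q-values filled by target-decoy counting.
    """
    databases = dict(databases or DEFAULT_DATABASES)
    for content in databases.values():
        if content not in DB_CONTENTS:
            raise ValueError(f"unknown database content {content!r}")
    rng = np.random.default_rng([config.seed, 202])
    model = config.score_model
    params = config.digestion

    index_all = build_index([human_db, bovine_db], params)
    human_accs = frozenset(human_db.accessions)
    bovine_accs = frozenset(bovine_db.accessions)
    fbs_accs = frozenset(lists.all_fbs)
    allowed = {
        "human": human_accs,
        "human+fbs": human_accs | fbs_accs,
        "human+bovine": human_accs | bovine_accs,
    }
    digests = _unique_peptides(human_db, params)
    digests.update(_unique_peptides(bovine_db, params))

    # db universes for drawing incorrect matches
    universe: dict[str, list[str]] = {}
    for content, accs in allowed.items():
        peps = sorted(
            {
                p
                for p in index_all.peptides()
                if any(acc in accs for acc, _ in index_all.parents(p))
            }
        )
        universe[content] = peps

    fbs_order = truth.major_fbs + truth.minor_fbs
    fbs_w = np.array([truth.fbs_weights[a] for a in fbs_order])
    fbs_w /= fbs_w.sum()
    human_order = sorted(human_accs)

    rows: dict[str, list[PSM]] = {label: [] for label in databases}
    for i in range(config.n_spectra):
        scan = i + 1
        charge = int(rng.choice([2, 3], p=[0.65, 0.35]))
        is_contaminant = rng.random() < config.contaminant_psm_fraction
        if is_contaminant:
            acc = str(fbs_order[int(rng.choice(len(fbs_order), p=fbs_w))])
            origin = "fbs"
        else:
            acc = str(human_order[int(rng.integers(len(human_order)))])
            origin = "human"
        peps = digests[acc]
        if not peps:
            continue  # pragma: no cover - length bounds make this unreachable
        peptide = str(peps[int(rng.integers(len(peps)))])
        parents = index_all.parents(peptide)
        parent_accs = {a for a, _ in parents}
        st = SpectrumTruth(
            scan=scan,
            origin=origin,
            source_accession=acc,
            peptide=peptide,
            in_human=bool(parent_accs & human_accs),
            in_fbs=bool(parent_accs & fbs_accs),
            in_bovine=bool(parent_accs & bovine_accs),
        )
        base_x = max(0.1, float(rng.normal(model.xcorr_correct_mean, model.xcorr_correct_sd)))
        for label, content in databases.items():
            present = sorted(parent_accs & allowed[content])
            wrong = rng.random() < config.incorrect_psm_rate
            if present and not wrong:
                x = base_x + float(rng.normal(0.0, model.db_noise_sd))
                # true source first when the database holds it
                ordered = ([acc] if acc in present else []) + [
                    a for a in present if a != acc
                ]
                rows[label].append(
                    PSM(
                        spectrum_file="synthetic.raw",
                        scan=scan,
                        charge=charge,
                        rank=1,
                        peptide=peptide,
                        modifications=(),
                        xcorr=round(max(0.05, x), 4),
                        q_value=None,
                        pep=model.pep_from_xcorr(x),
                        proteins=tuple(ordered),
                        search_db=label,
                    )
                )
                st.per_db[label] = "correct"
            elif wrong:
                pool = universe[content]
                fake = str(pool[int(rng.integers(len(pool)))])
                fake_parents = sorted(
                    a for a, _ in index_all.parents(fake) if a in allowed[content]
                )
                x = max(0.05, float(rng.normal(model.xcorr_incorrect_mean, model.xcorr_incorrect_sd)))
                rows[label].append(
                    PSM(
                        spectrum_file="synthetic.raw",
                        scan=scan,
                        charge=charge,
                        rank=1,
                        peptide=fake,
                        modifications=(),
                        xcorr=round(x, 4),
                        q_value=None,
                        pep=model.pep_from_xcorr(x),
                        proteins=tuple(fake_parents),
                        search_db=label,
                    )
                )
                st.per_db[label] = "incorrect"
            else:
                st.per_db[label] = "absent"
        truth.spectra[scan] = st

    # decoys: one per spectrum, scored from the incorrect distribution
    out: dict[str, PSMSet] = {}
    for label in databases:
        decoys = []
        for j in range(config.n_spectra):
            length = int(rng.integers(8, 16))
            pep_seq = _random_sequence(rng, length)
            x = max(
                0.05,
                float(
                    rng.normal(model.xcorr_incorrect_mean, model.xcorr_incorrect_sd)
                ),
            )
            decoys.append(
                PSM(
                    spectrum_file="synthetic.raw",
                    scan=1_000_000 + j + 1,
                    charge=int(rng.choice([2, 3])),
                    rank=1,
                    peptide=pep_seq,
                    modifications=(),
                    xcorr=round(x, 4),
                    q_value=None,
                    pep=model.pep_from_xcorr(x),
                    proteins=(f"DECOY_{j:05d}",),
                    search_db=label,
                    is_decoy=True,
                )
            )
        out[label] = estimate_q_values(PSMSet(rows[label] + decoys, label))
    return out


def generate_silac_annotations(
    config: SyntheticConfig, psms: PSMSet, truth: GroundTruth
) -> PSMSet:
    """Attach SILAC label modifications to a generated PSM table.

    Cell-derived (human-origin) spectra receive Arg10/Lys8 per residue at
    ``label_efficiency`` and Pro6 at ``pro_conversion_rate``; serum-derived
    (FBS-origin) spectra stay unlabeled.  Per-residue truth is recorded in
    ``truth.label_truth[search_db]``.  Decoy PSMs pass through unchanged.
    """
    salt = zlib.crc32(psms.search_db.encode()) % (2**16)
    rng = np.random.default_rng([config.seed, 303, salt])
    annotated: list[PSM] = []
    label_truth: dict[int, list[tuple[int, str, bool]]] = {}
    rates = {"R": config.label_efficiency, "K": config.label_efficiency,
             "P": config.pro_conversion_rate}
    mod_names = {"R": "Arg10", "K": "Lys8", "P": "Pro6"}
    for p in psms:
        if p.is_decoy:
            annotated.append(p)
            continue
        origin = truth.spectra[p.scan].origin
        mods: list[Modification] = []
        flags: list[tuple[int, str, bool]] = []
        for pos, aa in enumerate(p.peptide):
            if aa == "C":
                spec = SPEC_BY_NAME["Carbamidomethyl"]
                mods.append(Modification(pos, "C", spec.name, spec.delta_mass))
            if aa not in rates:
                continue
            labeled = origin == "human" and rng.random() < rates[aa]
            flags.append((pos, aa, labeled))
            if labeled:
                spec = SPEC_BY_NAME[mod_names[aa]]
                mods.append(Modification(pos, aa, spec.name, spec.delta_mass))
        label_truth[p.scan] = flags
        annotated.append(replace(p, modifications=tuple(mods)))
    truth.label_truth[psms.search_db] = label_truth
    return PSMSet(annotated, psms.search_db)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class Scenario:
    """One fully generated experiment: proteomes, tables, truth, indices."""

    config: SyntheticConfig
    human_db: SequenceDatabase
    bovine_db: SequenceDatabase
    fbs_db: SequenceDatabase
    lists: ContaminantLists
    truth: GroundTruth
    tables: dict[str, PSMSet]
    databases: dict[str, str]
    _indices: dict[str, PeptideIndex] = field(default_factory=dict)

    def index_for(self, label: str) -> PeptideIndex:
        """Peptide index over the named search database's content."""
        if label not in self._indices:
            content = self.databases[label]
            parts = {
                "human": [self.human_db],
                "human+fbs": [self.human_db, self.fbs_db],
                "human+bovine": [self.human_db, self.bovine_db],
            }[content]
            self._indices[label] = build_index(parts, self.config.digestion)
        return self._indices[label]

    @property
    def species_of(self) -> dict[str, Species]:
        out = self.human_db.species_map()
        out.update(self.bovine_db.species_map())
        return out


def generate_scenario(
    config: SyntheticConfig,
    databases: Mapping[str, str] | None = None,
    silac: bool = False,
) -> Scenario:
    """Generate proteomes and PSM tables in one call."""
    human_db, bovine_db, lists, truth = generate_proteomes(config)
    fbs_db = build_fbs_database(
        bovine_db, truth.major_fbs + truth.minor_fbs, name="FBS"
    )
    tables = generate_psm_tables(
        config, human_db, bovine_db, lists, truth, databases
    )
    if silac:
        tables = {
            label: generate_silac_annotations(config, table, truth)
            for label, table in tables.items()
        }
    return Scenario(
        config,
        human_db,
        bovine_db,
        fbs_db,
        lists,
        truth,
        tables,
        dict(databases or DEFAULT_DATABASES),
    )


def placeholder_database(
    n_entries: int,
    prefix: str,
    species: Species,
    name: str,
    sequence: str = "MKWVTFISLLLLFSSAYSRGVFRR",
) -> SequenceDatabase:
    """A database of ``n_entries`` placeholder records for entry-count
    arithmetic at realistic scale (sequence content is irrelevant there)."""
    records = [
        ProteinRecord(f"{prefix}{i:06d}", "placeholder", species, sequence, name)
        for i in range(n_entries)
    ]
    return SequenceDatabase(name, records, components=[(name, n_entries)])


def write_scenario(scenario: Scenario, outdir: str | Path) -> None:
    """Write a scenario to disk: FASTA, accession lists, PSM TSVs, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(scenario.human_db, outdir / "human.fasta")
    write_fasta(scenario.bovine_db, outdir / "bovine.fasta")
    write_fasta(scenario.fbs_db, outdir / "fbs.fasta")
    (outdir / "major_fbs.txt").write_text(
        "\n".join(scenario.truth.major_fbs) + "\n"
    )
    (outdir / "minor_fbs.txt").write_text(
        "\n".join(scenario.truth.minor_fbs) + "\n"
    )
    for label, table in scenario.tables.items():
        write_psm_table(table, outdir / f"psms_{label}.tsv")
    (outdir / "ground_truth.json").write_text(
        json.dumps(scenario.truth.to_dict(), indent=1)
    )
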