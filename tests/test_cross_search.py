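"""Species census, Venn partition and per-spectrum region classification."""

import math

import pytest

from contamsort import (
    ContaminantLists,
    DigestionParams,
    PSMSet,
    ProteinRecord,
    PsmClass,
    Region,
    SequenceDatabase,
    Species,
    build_index,
    census_protein_groups,
    census_psms,
    classify_psm,
    compare_searches,
    group_proteins,
    neg_log_pep,
    region_counts,
    venn_human_proteins,
)
from contamsort.cross_search import comparison_to_dataframe, plot_pep_comparison
from contamsort.errors import DatabaseMismatchError
from contamsort.psm_pipeline import GroupSpecies, ProteinGroup

from conftest import make_psm

LOOSE = DigestionParams(max_missed_cleavages=2, min_length=1, max_length=100)


def single(name, acc, sequence, species):
    return SequenceDatabase(name, [ProteinRecord(acc, "", species, sequence, name)])


@pytest.fixture(scope="module")
def small_world():
    """Two human proteins, three bovine (one major FBS, one minor, one
    other), one shared peptide, one utility protein."""
    human = SequenceDatabase(
        "h",
        [
            ProteinRecord("H1", "", Species.HUMAN, "TTTAYIAKELVISK", "h"),
            ProteinRecord("H2", "", Species.HUMAN, "QQWEDFGHC", "h"),
        ],
    )
    bovine = SequenceDatabase(
        "b",
        [
            ProteinRecord("BMAJ", "", Species.BOVINE, "CCCDFGHKELVISK", "b"),
            ProteinRecord("BMIN", "", Species.BOVINE, "GGGDFMHK", "b"),
            ProteinRecord("BOTH", "", Species.BOVINE, "WWWDFNHK", "b"),
        ],
    )
    utility = SequenceDatabase(
        "u", [ProteinRecord("UTIL1", "", Species.UTILITY, "MMMAYIDK", "u")]
    )
    index = build_index([human, bovine, utility], LOOSE)
    lists = ContaminantLists(frozenset({"BMAJ"}), frozenset({"BMIN"}))
    species_of = {
        **human.species_map(),
        **bovine.species_map(),
        **utility.species_map(),
    }
    return index, lists, species_of


class TestCensus:
    def test_classes(self, small_world):
        index, lists, species_of = small_world
        cases = [
            (make_psm(peptide="TTTAYIAK", proteins=("H1",)), PsmClass.HUMAN),
            # shared peptide is orthologous regardless of the reported protein
            (make_psm(peptide="ELVISK", proteins=("H1",)), PsmClass.ORTHOLOGOUS),
            (make_psm(peptide="ELVISK", proteins=("BMAJ",)), PsmClass.ORTHOLOGOUS),
            (make_psm(peptide="CCCDFGHK", proteins=("BMAJ",)), PsmClass.MAJOR_FBS),
            (make_psm(peptide="GGGDFMHK", proteins=("BMIN",)), PsmClass.MINOR_FBS),
            (make_psm(peptide="WWWDFNHK", proteins=("BOTH",)), PsmClass.OTHER_BOVINE),
            (make_psm(peptide="MMMAYIDK", proteins=("UTIL1",)), PsmClass.UTILITY),
        ]
        for psm, expected in cases:
            assert classify_psm(psm, index, lists, species_of) is expected

    def test_counts_partition_the_set(self, small_world):
        index, lists, species_of = small_world
        psms = PSMSet(
            [
                make_psm(scan=1, peptide="TTTAYIAK", proteins=("H1",)),
                make_psm(scan=2, peptide="ELVISK", proteins=("H1",)),
                make_psm(scan=3, peptide="CCCDFGHK", proteins=("BMAJ",)),
                make_psm(scan=4, peptide="QQWEDFGHC", proteins=("H2",)),
            ]
        )
        census = census_psms(psms, index, lists, species_of)
        assert census.total == 4
        assert sum(census.counts.values()) == census.total
        assert census.counts[PsmClass.HUMAN] == 2
        assert census.counts[PsmClass.ORTHOLOGOUS] == 1

    def test_unknown_protein_is_a_database_mismatch(self, small_world):
        index, lists, species_of = small_world
        stranger = make_psm(peptide="NOTINDEXED", proteins=("NOPE",))
        with pytest.raises(DatabaseMismatchError):
            classify_psm(stranger, index, lists, species_of)

    def test_group_census_by_leader(self, small_world):
        _, lists, _ = small_world
        groups = [
            ProteinGroup("H1", ("H1",), frozenset({"A"}), 1, GroupSpecies.HUMAN),
            ProteinGroup("H2", ("H2",), frozenset({"B"}), 1, GroupSpecies.HUMAN),
            ProteinGroup("H3", ("H3",), frozenset({"C"}), 1, GroupSpecies.HUMAN),
            ProteinGroup("BMAJ", ("BMAJ",), frozenset({"D"}), 1, GroupSpecies.BOVINE),
            ProteinGroup("MIX", ("MIX", "X2"), frozenset({"E"}), 1, GroupSpecies.AMBIGUOUS),
        ]
        counts = census_protein_groups(groups, lists)
        assert counts["human"] == 3
        assert counts["major_fbs"] == 1
        assert counts["ambiguous"] == 1


class TestVenn:
    def group(self, leader, species=GroupSpecies.HUMAN):
        return ProteinGroup(leader, (leader,), frozenset({f"PEP{leader}"}), 1, species)

    def test_identical_lists_have_empty_exclusives(self):
        groups = [self.group("P1"), self.group("P2")]
        venn = venn_human_proteins({"A": groups, "B": list(groups)})
        assert venn.only_in_a == venn.only_in_b == frozenset()
        assert venn.both == {"P1", "P2"}

    def test_set_algebra(self):
        a = [self.group(x) for x in ("P1", "P2", "P3")]
        b = [self.group(x) for x in ("P2", "P3", "P4")]
        venn = venn_human_proteins({"A": a, "B": b})
        assert venn.only_in_a == {"P1"}
        assert venn.only_in_b == {"P4"}
        assert venn.both == {"P2", "P3"}

    def test_shared_peptide_protein_flips_to_bovine_in_composite(self, small_world):
        """A human protein supported only by a shared peptide disappears from
        the human list once the composite database lets a bovine protein
        (with extra unique evidence) claim the peptide."""
        index, lists, species_of = small_world
        shared = "ELVISK"
        # human-only search: the shared peptide can only go to H1
        psms_hu = PSMSet([make_psm(scan=1, peptide=shared, proteins=("H1",))])
        # composite search: BMAJ has additional unique evidence and absorbs it
        psms_hf = PSMSet(
            [
                make_psm(scan=1, peptide=shared, proteins=("H1", "BMAJ")),
                make_psm(scan=2, peptide="CCCDFGHK", proteins=("BMAJ",)),
            ]
        )
        groups_hu = group_proteins(psms_hu, species_of)
        groups_hf = group_proteins(psms_hf, species_of)
        venn = venn_human_proteins({"HuDB": groups_hu, "HFDB": groups_hf})
        assert venn.only_in_a == {"H1"}
        assert venn.only_in_b == frozenset()


class TestCompare:
    def test_identical_pep_is_grey(self):
        a = PSMSet([make_psm(scan=1, pep=0.01)])
        b = PSMSet([make_psm(scan=1, pep=0.01)])
        (rec,) = compare_searches(a, b)
        assert rec.region is Region.GREY
        assert rec.delta == pytest.approx(0.0)

    def test_tenfold_pep_improvement_is_red(self):
        a = PSMSet([make_psm(scan=1, pep=0.5)])
        b = PSMSet([make_psm(scan=1, pep=0.05)])
        (rec,) = compare_searches(a, b)
        assert rec.delta == pytest.approx(1.0)
        assert rec.region is Region.RED

    def test_reverse_improvement_is_green(self):
        a = PSMSet([make_psm(scan=1, pep=0.05)])
        b = PSMSet([make_psm(scan=1, pep=0.5)])
        (rec,) = compare_searches(a, b)
        assert rec.region is Region.GREEN

    def test_b_only_is_blue_and_a_only_is_unmatched(self):
        a = PSMSet([make_psm(scan=1)])
        b = PSMSet([make_psm(scan=2)])
        regions = {r.spectrum_key[1]: r.region for r in compare_searches(a, b)}
        assert regions == {1: Region.A_ONLY_UNMATCHED, 2: Region.BLUE}

    def test_swapping_sides_maps_regions_symmetrically(self):
        a = PSMSet(
            [
                make_psm(scan=1, pep=0.5),
                make_psm(scan=2, pep=0.05),
                make_psm(scan=3, pep=0.01),
            ]
        )
        b = PSMSet(
            [
                make_psm(scan=1, pep=0.05),
                make_psm(scan=2, pep=0.5),
                make_psm(scan=4, pep=0.01),
            ]
        )
        forward = region_counts(compare_searches(a, b))
        backward = region_counts(compare_searches(b, a))
        assert forward["red"] == backward["green"]
        assert forward["green"] == backward["red"]
        assert forward["blue"] == backward["a_only_unmatched"]
        assert forward["grey"] == backward["grey"]

    def test_best_pep_wins_when_charges_differ(self):
        a = PSMSet(
            [make_psm(scan=1, charge=2, pep=0.2), make_psm(scan=1, charge=3, pep=0.01)]
        )
        b = PSMSet([make_psm(scan=1, pep=0.01)])
        (rec,) = compare_searches(a, b)
        assert rec.neglogpep_a == pytest.approx(neg_log_pep(0.01))

    def test_exact_duplicate_spectrum_is_an_error(self):
        a = PSMSet([make_psm(scan=1), make_psm(scan=1)])
        with pytest.raises(ValueError, match="duplicate"):
            compare_searches(a, PSMSet([]))

    def test_pep_floor_avoids_infinity(self):
        assert neg_log_pep(0.0) == pytest.approx(10.0)
        assert math.isfinite(neg_log_pep(1e-300))

    def test_dataframe_and_plot_outputs(self, tmp_path):
        a = PSMSet([make_psm(scan=1, pep=0.5), make_psm(scan=2, pep=0.01)])
        b = PSMSet([make_psm(scan=1, pep=0.05), make_psm(scan=3, pep=0.01)])
        records = compare_searches(a, b)
        df = comparison_to_dataframe(records)
        assert set(df["region"]) == {"red", "a_only_unmatched", "blue"}
        out = tmp_path / "scatter.png"
        plot_pep_comparison(records, path=out)
        assert out.stat().st_size > 0
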