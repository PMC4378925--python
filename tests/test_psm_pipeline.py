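"""PSM table IO, confidence filtering, protein grouping and q-values."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contamsort import (
    FilterCriteria,
    PSMSet,
    estimate_q_values,
    filter_protein_groups,
    filter_psms,
    group_proteins,
    read_psm_table,
    write_psm_table,
)
from contamsort.errors import MissingColumnError, ModificationParseError, NoDecoysError

from conftest import brute_force_min_cover_size, make_psm


class TestReadPsmTable:
    HEADER = "spectrum_file\tscan\tcharge\trank\tpeptide\tmodifications\txcorr\tq_value\tpep\tproteins\tsearch_db\n"

    def write(self, tmp_path, rows, header=None):
        path = tmp_path / "psms.tsv"
        path.write_text((header or self.HEADER) + "".join(rows))
        return path

    def row(self, scan, peptide="SAMPLER", mods="", proteins="P1;P2"):
        return f"run.raw\t{scan}\t2\t1\t{peptide}\t{mods}\t3.1\t0.001\t0.002\t{proteins}\tHuDB\n"

    def test_reads_one_psm_per_row(self, tmp_path):
        path = self.write(tmp_path, [self.row(i) for i in range(10)])
        psms = read_psm_table(path)
        assert len(psms) == 10
        assert psms[0].proteins == ("P1", "P2")
        assert psms[0].search_db == "HuDB"

    def test_oxidation_cell_parses_to_zero_based_position(self, tmp_path):
        path = self.write(tmp_path, [self.row(1, peptide="AAMK", mods="M3(Oxidation)")])
        mod = read_psm_table(path)[0].modifications[0]
        assert (mod.position, mod.name, mod.delta_mass) == (2, "Oxidation", 15.99)

    def test_missing_required_column_is_named(self, tmp_path):
        header = self.HEADER.replace("\tpeptide", "\tsequence_oops")
        path = self.write(tmp_path, [], header=header)
        with pytest.raises(MissingColumnError, match="peptide"):
            read_psm_table(path)

    def test_missing_pep_defers_error_to_the_step_that_needs_it(self, tmp_path):
        from contamsort import compare_searches

        header = self.HEADER.replace("\tpep\t", "\tnot_pep\t")
        path = self.write(tmp_path, [self.row(1)], header=header)
        psms = read_psm_table(path)  # reading succeeds
        assert psms[0].pep is None
        with pytest.raises(MissingColumnError, match="PEP"):
            compare_searches(psms, psms)

    def test_unparsable_modification_reports_row(self, tmp_path):
        path = self.write(tmp_path, [self.row(1), self.row(2, mods="garbage")])
        with pytest.raises(ModificationParseError, match="row 3"):
            read_psm_table(path)

    def test_pd_export_dialect_maps_vendor_columns(self, tmp_path):
        path = tmp_path / "export.csv"
        path.write_text(
            "Spectrum File,First Scan,Charge,Rank,Sequence,Modifications,"
            "XCorr,Percolator q-Value,Percolator PEP,Protein Accessions\n"
            "run.raw,42,3,1,SAMPLER,,2.9,0.004,0.01,P1;P2\n"
        )
        psms = read_psm_table(path, dialect="pd_export")
        assert len(psms) == 1
        assert psms[0].scan == 42 and psms[0].q_value == 0.004

    def test_write_read_round_trip(self, tmp_path):
        original = PSMSet(
            [make_psm(scan=1), make_psm(scan=2, peptide="ELVISK", xcorr=2.2)], "A"
        )
        path = tmp_path / "rt.tsv"
        write_psm_table(original, path)
        back = read_psm_table(path)
        assert [(p.scan, p.peptide, p.xcorr) for p in back] == [
            (p.scan, p.peptide, p.xcorr) for p in original
        ]


class TestFilterPsms:
    @pytest.mark.parametrize(
        "charge, xcorr, q, kept",
        [
            (2, 1.9, 0.005, False),  # below the +2 threshold of 2
            (2, 2.0, 0.005, True),
            (3, 2.30, 0.005, True),  # above the +3 threshold of 2.25
            (3, 2.20, 0.005, False),
            (9, 3.39, 0.005, False),  # the >+7 bucket applies
            (9, 3.41, 0.005, True),
            (2, 3.0, 0.02, False),  # q above 0.01
        ],
    )
    def test_charge_dependent_thresholds(self, charge, xcorr, q, kept):
        psms = PSMSet([make_psm(charge=charge, xcorr=xcorr, q=q)])
        assert (len(filter_psms(psms)) == 1) is kept

    def test_rank_two_removed_when_top_rank_only(self):
        psms = PSMSet([make_psm(rank=2)])
        assert len(filter_psms(psms)) == 0
        loose = dataclasses.replace(FilterCriteria(), top_rank_only=False)
        assert len(filter_psms(psms, loose)) == 1

    def test_empty_input_empty_output(self):
        assert len(filter_psms(PSMSet([]))) == 0

    def test_invalid_charge_rejected_at_construction(self):
        with pytest.raises(ValueError, match="charge"):
            make_psm(charge=0)

    def test_idempotent(self):
        psms = PSMSet([make_psm(scan=i, xcorr=1.5 + i * 0.2) for i in range(10)])
        once = filter_psms(psms)
        twice = filter_psms(once)
        assert [p.scan for p in twice] == [p.scan for p in once]

    def test_relaxing_any_criterion_is_monotone(self):
        psms = PSMSet(
            [
                make_psm(scan=i, charge=2 + i % 3, xcorr=1.0 + 0.3 * i,
                         q=0.002 * i, rank=1 + i % 2)
                for i in range(20)
            ]
        )
        base = FilterCriteria()
        n_base = len(filter_psms(psms, base))
        relaxed = [
            dataclasses.replace(base, q_max=0.05),
            dataclasses.replace(base, top_rank_only=False),
            dataclasses.replace(
                base,
                xcorr_min_by_charge={
                    k: v - 0.5 for k, v in base.xcorr_min_by_charge.items()
                },
            ),
        ]
        for criteria in relaxed:
            assert len(filter_psms(psms, criteria)) >= n_base


class TestGroupProteins:
    def psms_for(self, membership: dict[str, tuple[str, ...]]) -> PSMSet:
        """One PSM per peptide, proteins = the peptide's parents."""
        return PSMSet(
            [
                make_psm(scan=i + 1, peptide=pep, proteins=parents)
                for i, (pep, parents) in enumerate(sorted(membership.items()))
            ]
        )

    def test_single_protein_single_group(self):
        groups = group_proteins(self.psms_for({"PEPTIDEA": ("A",), "PEPTIDEB": ("A",)}))
        assert len(groups) == 1
        assert groups[0].leader == "A"
        assert groups[0].peptides == {"PEPTIDEA", "PEPTIDEB"}

    def test_subset_protein_absorbed(self):
        groups = group_proteins(
            self.psms_for({"PEPTIDEA": ("A",), "PEPTIDEB": ("A", "B")})
        )
        assert len(groups) == 1
        assert groups[0].leader == "A"
        assert groups[0].psm_count == 2

    def test_identical_evidence_merges_members(self):
        groups = group_proteins(self.psms_for({"PEPTIDEA": ("B", "A")}))
        assert len(groups) == 1
        assert groups[0].members == ("A", "B")
        assert groups[0].leader == "A"

    def test_greedy_trap_still_minimal(self):
        # a naive greedy cover picks the big set first and needs 3 groups
        membership = {
            "PEPA": ("BIG", "B1"),
            "PEPB": ("BIG", "B1"),
            "PEPC": ("BIG", "B2"),
            "PEPD": ("BIG", "B2"),
            "PEPE": ("B1",),
            "PEPF": ("B2",),
        }
        groups = group_proteins(self.psms_for(membership))
        assert sorted(g.leader for g in groups) == ["B1", "B2"]

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(data=st.data())
    def test_matches_brute_force_minimum_cover(self, data):
        n_prot = data.draw(st.integers(1, 6))
        n_pep = data.draw(st.integers(1, 8))
        peptides = [f"PEP{i:02d}" for i in range(n_pep)]
        proteins = [f"PR{j}" for j in range(n_prot)]
        membership: dict[str, tuple[str, ...]] = {}
        for pep in peptides:
            parents = data.draw(
                st.lists(st.sampled_from(proteins), min_size=1, unique=True)
            )
            membership[pep] = tuple(parents)
        groups = group_proteins(self.psms_for(membership))
        prot_peps: dict[str, set[str]] = {}
        for pep, parents in membership.items():
            for prot in parents:
                prot_peps.setdefault(prot, set()).add(pep)
        expected = brute_force_min_cover_size(
            {p: frozenset(s) for p, s in prot_peps.items()}
        )
        assert len(groups) == expected
        # every peptide assigned to exactly one group
        claimed = [pep for g in groups for pep in g.peptides]
        assert sorted(claimed) == sorted(membership)

    def test_protein_level_filtering(self):
        psms = self.psms_for({"PEPTIDEA": ("A",), "PEPTIDEB": ("A",)})
        groups = group_proteins(psms)
        # two PSMs at xcorr 3.0 give score 6.0 < 10 -> filtered out
        assert filter_protein_groups(groups, psms) == []
        loose = dataclasses.replace(FilterCriteria(), protein_score_min=5.0)
        assert len(filter_protein_groups(groups, psms, loose)) == 1


class TestEstimateQValues:
    def test_hand_computed_example(self):
        psms = PSMSet(
            [
                make_psm(scan=1, xcorr=10, q=None),
                make_psm(scan=2, xcorr=8, q=None),
                make_psm(scan=3, xcorr=6, q=None),
                make_psm(scan=4, xcorr=7, q=None, decoy=True, proteins=("DECOY_1",)),
            ]
        )
        out = estimate_q_values(psms)
        by_scan = {p.scan: p.q_value for p in out}
        assert by_scan[1] == 0.0
        assert by_scan[2] == 0.0
        assert by_scan[3] == pytest.approx(1 / 3)

    def test_separated_scores_give_zero_q(self):
        psms = PSMSet(
            [make_psm(scan=i, xcorr=5 + i, q=None) for i in range(5)]
            + [
                make_psm(scan=10 + i, xcorr=1 + 0.1 * i, q=None, decoy=True,
                         proteins=("DECOY_1",))
                for i in range(5)
            ]
        )
        out = estimate_q_values(psms)
        assert all(p.q_value == 0.0 for p in out.targets())

    def test_no_decoys_is_an_error(self):
        with pytest.raises(NoDecoysError):
            estimate_q_values(PSMSet([make_psm()]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        scores=st.lists(st.floats(0.1, 9.9), min_size=2, max_size=40),
        decoy_flags=st.lists(st.booleans(), min_size=2, max_size=40),
    )
    def test_q_monotone_in_score_and_bounded(self, scores, decoy_flags):
        n = min(len(scores), len(decoy_flags))
        flags = decoy_flags[:n]
        if not any(flags):
            flags[0] = True
        psms = PSMSet(
            [
                make_psm(scan=i, xcorr=scores[i], q=None, decoy=flags[i],
                         proteins=("DECOY_1",) if flags[i] else ("P1",))
                for i in range(n)
            ]
        )
        out = estimate_q_values(psms)
        ranked = sorted(out, key=lambda p: -p.xcorr)
        qs = [p.q_value for p in ranked]
        assert all(0.0 <= q <= 1.0 for q in qs)
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
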