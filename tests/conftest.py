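"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import pytest

from contamsort import PSM, SyntheticConfig, generate_scenario


def make_psm(
    peptide: str = "ACDEFK",
    scan: int = 1,
    charge: int = 2,
    xcorr: float = 3.0,
    q: float | None = 0.001,
    pep: float | None = 0.001,
    proteins=("P1",),
    rank: int = 1,
    mods=(),
    spectrum_file: str = "run.raw",
    decoy: bool = False,
    db: str = "A",
) -> PSM:
    return PSM(
        spectrum_file,
        scan,
        charge,
        rank,
        peptide,
        tuple(mods),
        xcorr,
        q,
        pep,
        tuple(proteins),
        db,
        decoy,
    )


def oracle_digest(
    sequence: str,
    max_missed: int,
    min_length: int = 1,
    max_length: int = 10**9,
    proline_rule: bool = True,
) -> set[tuple[int, int]]:
    """Brute-force tryptic digest: enumerate all substrings and keep those
    whose boundaries are valid tryptic termini with <= max_missed internal
    cleavage sites.  Returns (start, end) intervals."""
    n = len(sequence)

    def cleavable(i: int) -> bool:  # bond after residue i
        if i >= n - 1:
            return False
        if sequence[i] not in "KR":
            return False
        return not (proline_rule and sequence[i + 1] == "P")

    out = set()
    for start in range(n):
        if not (start == 0 or cleavable(start - 1)):
            continue
        for end in range(start + 1, n + 1):
            if not (end == n or cleavable(end - 1)):
                continue
            internal = sum(1 for i in range(start, end - 1) if cleavable(i))
            if internal <= max_missed and min_length <= end - start <= max_length:
                out.add((start, end))
    return out


def brute_force_min_cover_size(
    protein_peptides: dict[str, frozenset[str]],
) -> int:
    """Minimum number of proteins covering all peptides (exhaustive).

    Proteins with identical peptide sets count once, matching the grouping
    convention that indistinguishable proteins merge.
    """
    distinct = list({peps for peps in protein_peptides.values()})
    universe = frozenset(itertools.chain.from_iterable(distinct))
    for r in range(1, len(distinct) + 1):
        for combo in itertools.combinations(distinct, r):
            if frozenset(itertools.chain.from_iterable(combo)) >= universe:
                return r
    return len(distinct)


@pytest.fixture(scope="session")
def tiny_scenario():
    """A small but complete synthetic experiment shared across tests."""
    config = SyntheticConfig(
        seed=7,
        n_human_proteins=60,
        n_bovine_proteins=30,
        n_fbs_proteins=16,
        major_fbs_count=8,
        n_spectra=600,
        incorrect_psm_rate=0.02,
    )
    return generate_scenario(config, silac=True)
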