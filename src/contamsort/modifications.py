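"""Peptide modification parsing and the SILAC/search modification registry.

Modification strings follow the common spreadsheet-export convention:
semicolon-separated tokens like ``M3(Oxidation)`` (residue letter, 1-based
position, name) or ``N-Term(Acetyl)`` for terminal modifications.  Known
names carry their delta masses to two decimals as conventionally printed;
the isotope labels used for SILAC auditing are flagged ``is_label``:

* Arg10 on R (+10.01 Da), Lys8 on K (+8.01 Da) -- the heavy amino acids
  incorporated by SILAC-labelled cells;
* Pro6 on P (+6.01 Da) -- heavy proline arising from metabolic Arg->Pro
  conversion in eukaryotes;
* Carbamidomethyl on C (+57.02 Da) and Oxidation on M (+15.99 Da) -- the
  usual fixed/variable search modifications, not labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ModificationParseError


@dataclass(frozen=True)
class ModificationSpec:
    """A named modification: target residue, delta mass, label flag."""

    name: str
    residue: str
    delta_mass: float
    is_label: bool


DEFAULT_SPECS: tuple[ModificationSpec, ...] = (
    ModificationSpec("Arg10", "R", 10.01, True),
    ModificationSpec("Lys8", "K", 8.01, True),
    ModificationSpec("Pro6", "P", 6.01, True),
    ModificationSpec("Carbamidomethyl", "C", 57.02, False),
    ModificationSpec("Oxidation", "M", 15.99, False),
)

SPEC_BY_NAME: dict[str, ModificationSpec] = {s.name: s for s in DEFAULT_SPECS}

LABEL_SPECS: tuple[ModificationSpec, ...] = tuple(
    s for s in DEFAULT_SPECS if s.is_label
)


@dataclass(frozen=True)
class Modification:
    """One modification instance on a peptide.

    ``position`` is the 0-based residue index, or ``None`` for terminal
    modifications (then ``terminus`` is ``"N-Term"`` or ``"C-Term"``).
    ``delta_mass`` is ``None`` for names absent from the registry.
    """

    position: int | None
    residue: str | None
    name: str
    delta_mass: float | None = None
    terminus: str | None = None


_RESIDUE_RE = re.compile(r"^([A-Z])(\d+)\(([^()]+)\)$")
_TERM_RE = re.compile(r"^(N-Term|C-Term)\(([^()]+)\)$")


def parse_modifications(cell: str | None, row: int | None = None) -> list[Modification]:
    """Parse a modification cell into :class:`Modification` instances.

    Empty/missing cells yield an empty list.  Unparsable tokens raise
    :class:`ModificationParseError` (mentioning ``row`` when given).
    """
    if cell is None:
        return []
    cell = cell.strip()
    if not cell or cell.lower() in ("nan", "-"):
        return []
    mods: list[Modification] = []
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        m = _RESIDUE_RE.match(token)
        if m:
            residue, pos, name = m.group(1), int(m.group(2)), m.group(3)
            spec = SPEC_BY_NAME.get(name)
            mods.append(
                Modification(pos - 1, residue, name, spec.delta_mass if spec else None)
            )
            continue
        m = _TERM_RE.match(token)
        if m:
            terminus, name = m.group(1), m.group(2)
            spec = SPEC_BY_NAME.get(name)
            mods.append(
                Modification(
                    None, None, name, spec.delta_mass if spec else None, terminus
                )
            )
            continue
        where = f" (row {row})" if row is not None else ""
        raise ModificationParseError(f"unparsable modification {token!r}{where}")
    return mods


def format_modifications(mods: list[Modification]) -> str:
    """Inverse of :func:`parse_modifications` (canonical token order kept)."""
    tokens = []
    for mod in mods:
        if mod.terminus is not None:
            tokens.append(f"{mod.terminus}({mod.name})")
        else:
            tokens.append(f"{mod.residue}{mod.position + 1}({mod.name})")
    return ";".join(tokens)
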