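"""Exception hierarchy.

Everything raised deliberately by the package derives from
:class:`ContamSortError` so callers can catch one type at pipeline
boundaries.
"""


class ContamSortError(Exception):
    """Base class for all contamsort errors."""


class FastaParseError(ContamSortError):
    """Malformed FASTA input (bad header, empty sequence)."""


class DuplicateAccessionError(ContamSortError):
    """An accession occurs more than once within a single database."""


class AccessionCollisionError(ContamSortError):
    """Accessions collide across databases being merged under the strict policy."""


class MissingColumnError(ContamSortError):
    """A required column is absent from a PSM table."""


class ModificationParseError(ContamSortError):
    """A modification string could not be parsed."""


class DatabaseMismatchError(ContamSortError):
    """A PSM refers to proteins unknown to the supplied databases/index."""


class NoDecoysError(ContamSortError):
    """Target-decoy q-value estimation requested without any decoy PSMs."""


class LabelMismatchError(ContamSortError):
    """An isotope-label modification sits on a residue it cannot modify."""
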