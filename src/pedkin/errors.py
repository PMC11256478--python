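"""Exception hierarchy.

All package errors derive from :class:`PedkinError` so callers can catch one
base class. Validation problems (structure of the pedigree or of a query) are
kept distinct from alignment/contract problems (mis-sized resume vectors)
because the command-line layer maps them to different exit codes.
"""


class PedkinError(Exception):
    """Base class for all pedkin errors."""


class PedigreeParseError(PedkinError):
    """A pedigree file row could not be parsed (wrong column count etc.)."""


class PedigreeValidationError(PedkinError):
    """The pedigree violates a structural invariant (duplicates, roles...)."""


class CycleError(PedigreeValidationError):
    """An individual is its own ancestor; no chronological order exists."""


class OrderingError(PedigreeValidationError):
    """Strict mode: the input order violates parent-before-progeny."""


class RoleError(PedigreeValidationError):
    """A relationship query violates the sex-role constraints of its type."""


class DisjointnessError(PedigreeValidationError):
    """set1 and set2 of a relationship query overlap, or a set has duplicates."""


class UnknownCodeError(PedkinError, KeyError):
    """A referenced individual code/label does not exist in the pedigree."""


class AlignmentError(PedkinError):
    """A resume vector does not align with the ordered pedigree prefix."""


class DomainError(PedkinError, ValueError):
    """A numeric argument is outside its mathematical domain."""
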