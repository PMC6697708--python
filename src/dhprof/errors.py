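"""Exception hierarchy shared across the package."""


class DhprofError(Exception):
    """Base class for all errors raised by dhprof."""


class ParseError(DhprofError):
    """A coordinate or alignment file could not be parsed."""


class FormatError(DhprofError):
    """Input is syntactically readable but violates a format contract."""


class NotFoundError(DhprofError):
    """A requested chain, residue, ligand or atom does not exist."""


class ArgumentError(DhprofError):
    """An argument violates a documented precondition."""


class DegenerateSuperpositionError(DhprofError):
    """Fewer than three usable atom pairs survive for a rigid fit."""


class EmptyAlignmentError(DhprofError):
    """Occupancy refinement removed every column of the alignment."""


class ReferenceMismatchError(DhprofError):
    """The MSA reference row does not match the supplied chain sequence."""


class SpecError(DhprofError):
    """A synthetic-data specification is internally inconsistent."""
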