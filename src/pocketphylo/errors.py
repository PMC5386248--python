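"""Exception hierarchy.

Every error raised deliberately by the package derives from
:class:`PocketPhyloError`, so callers (and the CLI) can distinguish user /
data problems from genuine bugs.
"""


class PocketPhyloError(Exception):
    """Base class for all package errors."""


class FormatError(PocketPhyloError):
    """Malformed or inconsistent input file."""


class EmptyModelError(FormatError):
    """No atoms survived PDB parsing / filtering."""


class MalformedLineError(FormatError):
    """Unparseable record in a text format; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class DuplicateIdError(FormatError):
    pass


class IllegalCharacterError(FormatError):
    pass


class RaggedAlignmentError(FormatError):
    """Aligned input rows have unequal lengths; carries the offending ids."""

    def __init__(self, ids):
        super().__init__(f"alignment rows have unequal lengths: {sorted(ids)}")
        self.ids = list(ids)


class NoComparableColumnsError(PocketPhyloError):
    """All alignment columns were gap-excluded for a sequence pair."""


class SaturationError(PocketPhyloError):
    """p-distance too close to 1 for the Poisson correction."""


class TreeError(PocketPhyloError):
    pass


class GroupAssignmentError(PocketPhyloError):
    """Group seeds are intermixed so clade-based assignment is impossible."""


class GeometryError(PocketPhyloError):
    pass


class NoPocketError(GeometryError):
    pass


class LowIdentityError(PocketPhyloError):
    """A structure's extracted sequence does not match the given sequence."""


class ZeroVarianceError(PocketPhyloError):
    pass


class ConfigError(PocketPhyloError):
    pass
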