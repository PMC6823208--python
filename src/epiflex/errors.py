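"""Exception hierarchy. Each class maps to a distinct CLI exit code."""


class EpiflexError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class StructureParseError(EpiflexError):
    """A structure file could not be parsed (message names the line)."""

    exit_code = 3


class StructuralMismatchError(EpiflexError):
    """Residue labelling differs between inputs that must share a topology."""

    exit_code = 4


class NumberingLookupError(EpiflexError, LookupError):
    """A residue is not covered by the numbering map."""

    exit_code = 5


class LoopResolutionError(EpiflexError):
    """A loop definition references residues absent from a profile/frame."""

    exit_code = 5


class InsufficientDataError(EpiflexError):
    """Too few frames/replicas/residues for the requested statistic."""

    exit_code = 6


class DegenerateGeometryError(EpiflexError):
    """Coordinates too ill-conditioned for a unique superposition."""

    exit_code = 7
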