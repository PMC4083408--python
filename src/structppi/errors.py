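"""Exception hierarchy shared across the pipeline."""


class StructPPIError(Exception):
    """Base class for all package errors."""


class EmptyStructureError(StructPPIError):
    """A structure or chain with no usable protein atoms."""


class GeometryError(StructPPIError):
    """Degenerate or mismatched coordinate input."""


class NoInterfaceError(StructPPIError):
    """Two chains share no contacting residue pair."""


class LibraryError(StructPPIError):
    """Template library is empty, malformed, or of an unknown version."""


class FormatError(StructPPIError):
    """Tabular input is missing mandatory columns or has bad values."""


class MutationParseError(FormatError):
    """A protein-change string does not parse as <AA><pos><AA|*>."""


class MappingError(StructPPIError):
    """Mutation-to-structure mapping failed an identity check."""


class TotalTruncationError(StructPPIError):
    """A nonsense truncation would delete every modelled residue."""
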