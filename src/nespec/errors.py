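"""Exception hierarchy shared across the pipeline stages."""


class NespecError(Exception):
    """Base class for all package-specific errors."""


class UnknownAtomError(NespecError, KeyError):
    """An atom label referenced by a dihedral/distance spec is absent from the frame."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the plain message
        return Exception.__str__(self)


class DegenerateGeometryError(NespecError, ValueError):
    """Three consecutive atoms of a torsion quadruple are (near-)collinear."""


class NoDataError(NespecError, ValueError):
    """An operation was asked to act on an empty series/stream/ensemble."""


class ParseError(NespecError, ValueError):
    """A line of an input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(NespecError, ValueError):
    """Input data violated a structural invariant (tags, signs, cross-checks)."""


class EmptyWindowError(NespecError, ValueError):
    """A dihedral window selected no conformers."""


class GenerationError(NespecError, ValueError):
    """Synthetic-data parameters produced physically impossible records."""
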