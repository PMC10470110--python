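"""Exception hierarchy shared across the package."""


class PentagenError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(PentagenError):
    """File is not in a supported on-disk format (wrong magic or mode byte)."""


class CorruptFileError(PentagenError):
    """File payload is inconsistent with its declared dimensions."""


class DimensionError(PentagenError, ValueError):
    """Operand shapes are mutually inconsistent."""


class DomainError(PentagenError, ValueError):
    """A value lies outside its admissible domain (e.g. dosage not in {0,1,2})."""


class OrientationError(PentagenError):
    """A packed matrix has the wrong orientation for the requested product."""


class PedigreeError(PentagenError):
    """Pedigree is structurally invalid (cycles, unknown animals)."""


class FactorizationError(PentagenError):
    """A required matrix factorization failed (e.g. singular A^nn)."""


class DegeneratePanelError(PentagenError):
    """The marker panel carries no polymorphism (scaling constant m == 0)."""


class ParameterError(PentagenError, ValueError):
    """A model parameter is outside its admissible range."""


class DivergenceError(PentagenError):
    """Iterative solver produced a non-finite residual."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration
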