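"""Exception hierarchy for oligoscope."""


class OligoscopeError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(OligoscopeError):
    """A coordinate file could not be parsed."""


class EmptyStructureError(OligoscopeError):
    """No atoms remain after filtering (waters/hydrogens removed)."""


class UnknownElementError(OligoscopeError):
    """An element has no tabulated hard-sphere radius and no default is allowed."""


class SymmetryError(OligoscopeError):
    """The structure does not define a ring oligomer (e.g. a single chain)."""


class AmbiguousSideError(OligoscopeError):
    """N- and C-terminal faces cannot be distinguished (identical mean z)."""


class MissingChromophoreError(OligoscopeError):
    """No retinal (or configured chromophore) residue found."""


class ChromophoreGeometryError(OligoscopeError):
    """A retinal residue lacks the atoms needed to define its dipole axis."""


class DegenerateFitError(OligoscopeError):
    """Geometry does not constrain the fit (e.g. collinear peaks)."""


class FilterError(OligoscopeError):
    """Invalid low-pass filter request (e.g. cutoff below Nyquist)."""


class AnalysisError(OligoscopeError):
    """A height-map analysis step received invalid inputs."""


class ExcitonError(OligoscopeError):
    """Invalid chromophore geometry or coupling matrix."""


class PackingError(OligoscopeError):
    """Rings could not be placed in the patch at the requested gap."""

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved


class ConfigError(OligoscopeError):
    """A pipeline run configuration failed validation."""
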