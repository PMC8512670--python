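"""Exception taxonomy shared across the package."""


class HydraShellError(Exception):
    """Base class for all package errors."""


class ParseError(HydraShellError):
    """Malformed input file (bad header, truncated frame, unknown layout)."""


class StructuralError(HydraShellError):
    """Input violates a structural contract (e.g. atom count varies)."""


class ContentError(HydraShellError):
    """Input is well-formed but its content is invalid (e.g. non-monotone k)."""


class DomainError(HydraShellError):
    """Arguments outside the operation's domain."""


class CapabilityError(HydraShellError):
    """The input lacks data the operation requires (e.g. missing dipoles)."""


class GridError(HydraShellError):
    """Mismatched or incompatible numerical grids."""


class StateError(HydraShellError):
    """Operation incompatible with the object's recorded state."""


class NoMinimumError(DomainError):
    """A radial profile has no interior minimum in the search window."""


class FitError(HydraShellError):
    """A model fit failed or is ill-posed; carries diagnostics in args."""


class ConfigurationError(HydraShellError):
    """Invalid generator or pipeline configuration."""
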