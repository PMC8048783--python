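"""Exception hierarchy shared by all analysis stages."""


class P450KitError(Exception):
    """Base class for all package-specific errors."""


class StructuralMismatchError(P450KitError):
    """Frames of a trajectory disagree on the atom roster."""


class ParseError(P450KitError):
    """A structure or table file could not be parsed."""


class SchemaError(P450KitError):
    """Tabular input is missing required columns or keys."""


class SelectionSyntaxError(P450KitError):
    """An atom-selection expression is malformed."""


class DegenerateGeometryError(P450KitError):
    """Geometric operation on coincident or zero-length vectors."""


class InsufficientPointsError(P450KitError):
    """Too few points for a superposition or fit."""


class ConfigurationError(P450KitError):
    """An analysis criterion or site definition is inconsistent."""


class InsufficientDataError(P450KitError):
    """Not enough observations to estimate the requested quantity."""


class FitFailureError(P450KitError):
    """A nonlinear fit failed to converge; diagnostics in the message."""


class DomainError(P450KitError):
    """A numeric argument is outside its physical domain."""


class DegenerateBasisError(P450KitError):
    """Spectral unmixing bases are linearly dependent on the grid."""


class LookupError_(P450KitError):
    """A named atom could not be resolved; message lists candidates."""
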