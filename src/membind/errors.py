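"""Exception hierarchy shared across the analysis stages."""


class MembindError(Exception):
    """Base class for all package errors."""


class InvalidProtocolError(MembindError):
    """An experimental protocol (titration schedule, trace sampling, ...) is unusable."""


class DegenerateDataError(MembindError):
    """Input data carry no information about the parameter being fitted."""


class FitFailureError(MembindError):
    """A nonlinear fit failed to converge; carries diagnostics.

    Attributes
    ----------
    diagnostics : dict
        Solver message, number of restarts attempted, last parameter vector.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InvalidAccessibilityError(MembindError):
    """Power-saturation shifts are non-positive: the depth parameter is undefined."""


class CalibrationError(MembindError):
    """Depth-calibration pairs cannot support a monotone calibration curve."""


class MissingAtomError(MembindError):
    """A residue lacks an atom required for label placement (e.g. glycine Cb)."""


class SchemaError(MembindError):
    """A tabular input does not match its declared schema."""
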