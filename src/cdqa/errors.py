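"""Exception hierarchy for the QA pipelines."""


class CdqaError(Exception):
    """Base class for all package errors."""


class LayoutError(CdqaError):
    """A region rectangle is inconsistent with the frame or another region."""


class FormatError(CdqaError):
    """Input frames are unreadable or mutually inconsistent."""


class PartitionError(CdqaError):
    """Frame partitioning into average images is infeasible (N*M > n_fr)."""


class ParameterError(CdqaError):
    """A method setting is out of its valid range."""


class NoFlowError(CdqaError):
    """No color-coded flow pixels where the method requires them."""


class GeometryError(CdqaError):
    """A constructed axis/segment falls outside the usable image region."""


class LumenNotFoundError(CdqaError):
    """No dark vessel lumen detected in the B-mode image."""


class CalibrationError(CdqaError):
    """Colorbar calibration failed (strip too small or degenerate)."""


class DegenerateInputError(CdqaError):
    """An estimator received inputs that make its formula undefined."""


class SpecError(CdqaError):
    """A synthetic phantom specification is not renderable."""


class McsError(CdqaError):
    """Monte-Carlo simulation failed (too many failed iterations)."""
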