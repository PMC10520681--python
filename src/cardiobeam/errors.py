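"""Exception hierarchy for cardiobeam."""


class CardiobeamError(Exception):
    """Base class for all cardiobeam errors."""


class ModelValidityError(CardiobeamError, ValueError):
    """Input state violates a validity limit of the small-deflection beam model."""


class StabilityError(CardiobeamError, ValueError):
    """Time step too coarse (or timebase malformed) for the forward integrator."""


class CalibrationError(CardiobeamError, ValueError):
    """Magnet calibration input is degenerate or non-monotone beyond tolerance."""


class TrackingLostError(CardiobeamError, RuntimeError):
    """The cantilever silhouette could not be located in one or more frames."""


class InsufficientExtentError(CardiobeamError, ValueError):
    """Too few midline columns to support a quadratic fit."""


class FitError(CardiobeamError, RuntimeError):
    """Ill-conditioned or failed per-frame polynomial fit."""


class RenderError(CardiobeamError, ValueError):
    """Synthetic scene does not fit in the requested frame geometry."""


class AnalysisError(CardiobeamError, ValueError):
    """Contractility analysis preconditions not met."""
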