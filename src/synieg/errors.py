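"""Exception types shared across the package."""


class SynIEGError(Exception):
    """Base class for package errors."""


class ValidationError(SynIEGError, ValueError):
    """Invalid user input: bad parameter values, malformed schedules, schema violations."""


class AnalysisError(SynIEGError, RuntimeError):
    """A computation could not produce a result (non-convergence, infeasibility)."""


class CalibrationError(AnalysisError):
    """Parameter calibration could not satisfy the requested constraints."""
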