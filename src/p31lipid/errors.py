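"""Exception hierarchy.

Every declared error path in the public API raises a subclass of
:class:`P31LipidError`; the CLI maps these to one-line diagnostics and a
nonzero exit code.
"""


class P31LipidError(Exception):
    """Base class for all package errors."""


class ValidationError(P31LipidError):
    """An argument violates a documented precondition."""


class ConfigurationError(P31LipidError):
    """Packaged or user-supplied configuration is missing or corrupt."""


class FormatError(P31LipidError):
    """An input file does not conform to its declared dialect."""


class CalibrationError(P31LipidError):
    """No usable reference peak found in the calibration window."""


class EstimationError(P31LipidError):
    """A statistical estimate cannot be formed from the given data."""


class EmptyReportError(P31LipidError):
    """Every row of a quantification report was excluded by the filters."""
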