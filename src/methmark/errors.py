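"""Exception types shared across the pipeline stages."""


class MethmarkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MethmarkError, ValueError):
    """A simulation or analysis configuration violates one of its bounds."""


class CalibrationError(MethmarkError, RuntimeError):
    """A requested (mean, sd) target is infeasible for the generating family."""


class DegenerateDataError(MethmarkError, ValueError):
    """Input data carry no information for the requested test."""


class SchemaError(MethmarkError, ValueError):
    """A delimited input file is missing required columns or has bad rows."""


class QCError(MethmarkError, ValueError):
    """A run-control record required for batch QC is missing or malformed."""
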