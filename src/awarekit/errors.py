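"""Exception types shared across the package."""


class AwarekitError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(AwarekitError):
    """Experimental design specification is internally inconsistent."""


class ConfigurationError(AwarekitError):
    """A configuration value is missing or malformed."""


class DegenerateInputError(AwarekitError):
    """Input data are too sparse or degenerate for the requested statistic."""


class ConvergenceError(AwarekitError):
    """An iterative fit failed its convergence diagnostics."""
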