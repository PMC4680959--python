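"""Package-wide exception types."""


class OsnPipeError(Exception):
    """Base class for all osnpipe errors."""


class ConfigurationError(OsnPipeError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(OsnPipeError):
    """A malformed input file; the message locates the offending record."""


class FitError(OsnPipeError):
    """A model fit failed or is degenerate beyond repair."""
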