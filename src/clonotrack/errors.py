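"""Exception types shared across the package."""


class ClonotrackError(Exception):
    """Base class for all package-specific errors."""


class RepertoireFormatError(ClonotrackError):
    """The input table does not conform to the expected dialect."""


class RepertoireParseError(ClonotrackError):
    """A cell could not be parsed; the message names the offending row."""


class EmptyRepertoireError(ClonotrackError):
    """An operation produced or received a repertoire with no records."""


class ConfigurationError(ClonotrackError):
    """Invalid parameter value or infeasible simulation configuration."""
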