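"""Exception hierarchy.

All errors raised on bad user input derive from :class:`CrossFuseError`
(itself a ``ValueError``) so callers can catch one type at the CLI boundary.
"""


class CrossFuseError(ValueError):
    """Base class for all crossfuse errors."""


class FormatError(CrossFuseError):
    """A file could not be parsed or its pieces disagree in shape."""


class DataError(CrossFuseError):
    """Parsed values are invalid (NaN/inf entries, empty inputs)."""


class ConfigError(CrossFuseError):
    """A configuration field is out of range or unknown."""


class ParameterError(CrossFuseError):
    """An operation parameter is incompatible with the data it was given."""
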