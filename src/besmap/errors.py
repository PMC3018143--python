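"""Exception hierarchy shared across the package."""


class BesmapError(Exception):
    """Base class for all besmap errors."""


class ConfigurationError(BesmapError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


class ParseError(BesmapError, ValueError):
    """A malformed input record; the message carries the source line number."""


class QueryIdError(BesmapError, ValueError):
    """A query id does not follow the configured clone/end naming convention."""


class ValidationError(BesmapError, ValueError):
    """An output record fails a coordinate or bookkeeping sanity check."""


class ContractError(BesmapError, RuntimeError):
    """An internal invariant was violated (indicates a caller or library bug)."""
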