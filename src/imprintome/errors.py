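"""Exception hierarchy shared across the pipeline stages."""


class ImprintomeError(Exception):
    """Base class for all package errors."""


class ParseError(ImprintomeError):
    """A malformed input record; the message names the offending site/line."""


class ConfigurationError(ImprintomeError):
    """An invalid configuration: missing sample, bad threshold, absent file."""


class ContractError(ImprintomeError):
    """An operation was called outside its preconditions."""
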