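"""Exception hierarchy shared across the toolkit."""


class BurdenKitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(BurdenKitError):
    """An input file could not be parsed (names the offending line/row)."""


class ValidationError(BurdenKitError):
    """Parsed data violates a domain invariant."""


class ConfigurationError(BurdenKitError):
    """Rule/model wiring is inconsistent (missing rule, cycle, orphan)."""
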