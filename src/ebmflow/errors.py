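"""Exception hierarchy for cohort validation and modelling errors."""


class EbmflowError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EbmflowError):
    """A mandatory column or config key is missing or malformed."""


class ParseError(EbmflowError):
    """A cell could not be coerced to the expected type."""


class ValidationError(EbmflowError):
    """Data violates a documented invariant (duplicate ids, bad groups, ...)."""
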