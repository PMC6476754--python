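"""Exception hierarchy shared across the pipeline."""


class ChplexError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ChplexError):
    """A file could not be parsed; the message names the offending record/row."""


class ValidationError(ChplexError):
    """Parsed data violate a structural invariant (lengths, vocabularies, ids)."""
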