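"""Exception hierarchy.

``FormatError`` marks malformed input files (bad columns, unparseable
fields); ``ValidationError`` marks inputs that parse but violate a domain
contract (duplicate keys, out-of-range frequencies, unknown tokens).
"""


class ExosfError(Exception):
    """Base class for all package errors."""


class FormatError(ExosfError):
    """Input file does not conform to the expected format."""


class ValidationError(ExosfError):
    """Parsed input violates a domain contract."""
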