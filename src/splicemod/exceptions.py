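"""Exception hierarchy for splicemod."""


class SpliceModError(Exception):
    """Base class for all splicemod errors."""


class ParseError(SpliceModError, ValueError):
    """A file could not be parsed; the message names the offending line/cell."""


class ValidationError(SpliceModError, ValueError):
    """A value or container violates a documented invariant."""
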