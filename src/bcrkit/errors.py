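"""Exception hierarchy shared across the toolkit."""


class BcrkitError(Exception):
    """Base class for all bcrkit errors."""


class FormatError(BcrkitError):
    """Input table does not conform to the expected IMGT/flat dialect."""


class UsageError(BcrkitError):
    """Invalid argument combination or parameter value."""


class EmptyInputError(BcrkitError):
    """An operation that requires data received none."""


class ParseError(BcrkitError):
    """A field could not be parsed; carries the offending raw text."""

    def __init__(self, message: str, raw: str = ""):
        super().__init__(message)
        self.raw = raw
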