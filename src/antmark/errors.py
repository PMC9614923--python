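"""Exception hierarchy shared across the toolkit."""


class AntmarkError(Exception):
    """Base class for all toolkit errors."""


class ParseError(AntmarkError, ValueError):
    """A text file or name could not be parsed (malformed line, bad grammar)."""


class FormatError(ParseError):
    """A name does not match the expected grammar (e.g. image-set folder names)."""


class IntegrityError(AntmarkError, ValueError):
    """Data violates a structural invariant (duplicate keys, clashing IDs)."""


class DomainError(AntmarkError, ValueError):
    """A value lies outside its valid domain (frame index, angle, rate)."""


class RangeError(DomainError):
    """A frame index lies outside the sequence."""


class FootprintError(DomainError):
    """Camera geometry with an unbounded ground footprint (alpha + beta >= 90 deg)."""


class UndefinedStatisticError(AntmarkError, ValueError):
    """A summary statistic was requested on an empty collection."""
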