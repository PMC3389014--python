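"""Exception types raised by the svmorph pipeline."""


class SvmorphError(Exception):
    """Base class for all svmorph errors."""


class StatsFormatError(SvmorphError):
    """A stats file is missing a required column or header."""


class StatsParseError(SvmorphError):
    """A stats file data row could not be parsed."""


class ValidationError(SvmorphError):
    """Input data violates a pipeline contract."""
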