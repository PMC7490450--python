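"""Exception hierarchy shared by all mirip modules.

Every error raised on user input derives from :class:`MiripError`, so callers
(and the CLI) can distinguish domain failures from programming bugs.
"""


class MiripError(Exception):
    """Base class for all mirip domain errors."""


class FormatError(MiripError):
    """A file or symbol does not conform to the documented dialect."""


class ValidationError(MiripError):
    """An input violates a stated invariant (range, uniqueness, emptiness)."""


class MissingDataError(MiripError):
    """A required value or measurement is absent."""


class NoAmplificationError(MiripError):
    """A Ct value required for the computation never amplified."""


class DegenerateInputError(MiripError):
    """The statistic is undefined on this input (zero variance, no events)."""


class SampleSizeError(MiripError):
    """Too few observations for the requested statistic."""


class MiripIOError(MiripError):
    """A file could not be read or written."""
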