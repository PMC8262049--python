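"""Exception hierarchy for the toolkit.

All errors raised deliberately by this package derive from
:class:`PoresigError`, so callers can catch one base class at pipeline
boundaries while still distinguishing failure modes.
"""


class PoresigError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PoresigError):
    """A file does not conform to the supported Fast5 dialect."""


class DuplicateReadError(PoresigError):
    """Two Fast5 files in one directory carry the same read id."""


class ExtractionError(PoresigError):
    """An events table row points outside its read's signal array."""


class SamplingError(PoresigError):
    """A sampling request cannot be satisfied by the available population."""


class PatternError(PoresigError):
    """A k-mer search pattern contains characters outside {A,C,G,T,*}."""


class ParameterError(PoresigError):
    """A numeric parameter is outside its admissible interval."""


class DegenerateInputError(PoresigError):
    """A statistical test received input on which it is undefined."""


class RangeError(PoresigError):
    """A reference coordinate falls outside an alignment's span."""


class IdentityError(PoresigError):
    """A read and an alignment that must describe the same molecule do not."""
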