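"""Exception hierarchy.

Everything derives from :class:`YstrError` so callers can catch the
package's failures with one clause; the subclasses mirror the distinct
failure modes of the pipeline (parsing, validation, state machine,
insufficient data, undefined statistics).
"""


class YstrError(Exception):
    """Base class for all ystrpop errors."""


class ParseError(YstrError, ValueError):
    """A file could not be parsed (names the offending row/column)."""


class ValidationError(YstrError, ValueError):
    """Input data violates a domain invariant."""


class StateError(YstrError, RuntimeError):
    """Operation applied to a table in the wrong state (e.g. double
    normalization, or a statistic that requires a normalized panel)."""


class InsufficientSampleError(YstrError, ValueError):
    """Too few (complete) records for the requested statistic."""


class UndefinedStatisticError(YstrError, ValueError):
    """The statistic is undefined on this input (e.g. Rst with zero
    total variance, or a frequency with zero denominator)."""
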