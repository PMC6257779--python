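"""Exception hierarchy.

Everything derives from :class:`LagnetError` so callers can catch the
package's failures with one clause; the subclasses map onto the distinct
failure modes of the pipeline (bad parameters, malformed files, series too
short for regression, mismatched gene panels, degenerate statistics).
"""


class LagnetError(Exception):
    """Base class for all errors raised by lagnet."""


class ParameterError(LagnetError, ValueError):
    """An argument is outside its valid range or inconsistent with others."""


class FormatError(LagnetError, ValueError):
    """An input file or in-memory table violates the expected format."""


class InsufficientDataError(LagnetError, ValueError):
    """Too few time points / transitions for the requested operation."""


class AlignmentError(LagnetError, ValueError):
    """Two objects that must share a gene panel do not."""


class UndefinedScoreError(LagnetError, ValueError):
    """A score (e.g. relative diversity with zero mean) is undefined."""


class ExperimentError(LagnetError, RuntimeError):
    """A sweep produced no usable result (every entry failed)."""
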