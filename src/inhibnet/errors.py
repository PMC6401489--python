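"""Exception hierarchy for inhibnet.

All library-raised errors derive from :class:`InhibnetError` so callers can
catch the package's failures with a single except clause; the more specific
subclasses mirror the distinct failure modes of the pipeline (malformed input,
inconsistent multi-condition data, undefined statistics, bad configuration).
"""


class InhibnetError(Exception):
    """Base class for all inhibnet errors."""


class MatrixFormatError(InhibnetError, ValueError):
    """An input matrix cell or table violates the binary inhibition format."""


class ConsistencyError(InhibnetError, ValueError):
    """Multi-condition inputs disagree (strain sets, reciprocity claims, ...)."""


class ConflictError(InhibnetError, ValueError):
    """Duplicate records assert contradictory values for the same cell."""


class UndefinedStatisticError(InhibnetError, ArithmeticError):
    """A statistic is undefined on this input (e.g. asymmetry of an edgeless graph)."""


class ConfigurationError(InhibnetError, ValueError):
    """Invalid analysis or generator configuration."""


class FeasibilityError(InhibnetError, RuntimeError):
    """A constrained randomization or generation problem has no solution."""
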