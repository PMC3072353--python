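"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes):

* :class:`ValidationError` — the input is malformed or out of contract
  (bad file, bad value, bad configuration).
* :class:`DegenerateStatisticsError` — the input is well formed but the
  requested statistic is undefined on it (single-class labels, zero
  variance, inverted class orientation).
"""


class RBRatioError(Exception):
    """Base class for all package errors."""


class ValidationError(RBRatioError):
    """Input violates a structural or value contract."""


class ParseError(ValidationError):
    """A cell or field failed to parse; the message carries coordinates."""


class StructureError(ValidationError):
    """File-level structure is wrong (ragged rows, missing columns)."""


class RangeError(ValidationError):
    """A value lies outside its admissible range."""


class FormatError(ValidationError):
    """A line does not conform to the expected dialect."""


class ConfigError(ValidationError):
    """A simulation or pipeline configuration violates its invariants."""


class DomainError(ValidationError):
    """Arguments to a statistical function violate its domain."""


class DegenerateStatisticsError(RBRatioError):
    """The requested statistic is undefined on this input."""


class InsufficientDataError(DegenerateStatisticsError):
    """Too few observations to compute the statistic."""


class DegeneratePhenotypeError(DegenerateStatisticsError):
    """Phenotype labels contain a single class."""


class DegenerateMetricError(DegenerateStatisticsError):
    """The correlation metric is undefined on all-constant input."""


class OrientationError(DegenerateStatisticsError):
    """Class means are oriented against the biologically fixed direction."""
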