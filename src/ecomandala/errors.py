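"""Named exceptions and warnings shared across the pipeline.

Every user-facing failure mode has its own class so callers (and the CLI)
can react to, or report, the precise problem.
"""


class EcoMandalaError(Exception):
    """Base class for all package errors."""


# --- table I/O and validation -------------------------------------------------

class MissingFileError(EcoMandalaError, FileNotFoundError):
    """Input file does not exist."""


class NonNumericCellError(EcoMandalaError, ValueError):
    """An abundance cell could not be parsed as a number (names row/column)."""


class DuplicateIdError(EcoMandalaError, ValueError):
    """Duplicate OTU (or site) identifier where uniqueness is required."""


class EmptyTableError(EcoMandalaError, ValueError):
    """A table with a header but no data rows (or no columns)."""


class MissingColumnError(EcoMandalaError, ValueError):
    """A required column (e.g. otu_id or a taxonomic rank) is absent."""


class RankOrderError(EcoMandalaError, ValueError):
    """Taxonomy ranks present but not in kingdom...genus order."""


class PhylumNotFoundError(EcoMandalaError, KeyError):
    """Requested phylum does not occur in the taxonomy."""


class UnknownOTUError(EcoMandalaError, KeyError):
    """An OTU id is not present in the taxonomy table."""


# --- series / estimation ------------------------------------------------------

class ZeroVarianceError(EcoMandalaError, ValueError):
    """A constant series cannot be z-normalized."""


class SeriesLengthError(EcoMandalaError, ValueError):
    """Time series too short (or mismatched) for the requested estimator."""


class TooFewTailPointsError(EcoMandalaError, ValueError):
    """Fewer tail observations than the configured minimum (n_min)."""


class DegenerateTailError(EcoMandalaError, ValueError):
    """Tail has zero spread (all values equal), so the MLE is undefined."""


class TooFewPointsError(EcoMandalaError, ValueError):
    """Not enough usable (mean, variance) points for the Taylor regression."""


class NoPairsError(EcoMandalaError, ValueError):
    """A distance summary was requested but no tip pairs exist."""


class AxisValueError(EcoMandalaError, ValueError):
    """Axis rescaling got no finite positive value (or NaN)."""


class IncalculableError(EcoMandalaError, ValueError):
    """No entity (site/phylum) had all required quantities calculable."""


class ConfigError(EcoMandalaError, ValueError):
    """Invalid or unknown configuration key/value."""


# --- warnings -----------------------------------------------------------------

class ShortSeriesWarning(UserWarning):
    """Time series shorter than 10 points: estimates are very noisy."""


class ExperimentalWarning(UserWarning):
    """A parameter combination outside the validated default settings."""
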