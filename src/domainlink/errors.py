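"""Exception hierarchy for the domainlink pipeline.

Every pipeline-specific failure derives from :class:`DomainlinkError` so
callers (and the CLI) can distinguish domain errors from programming errors.
"""


class DomainlinkError(Exception):
    """Base class for all domainlink errors."""


class ConfigError(DomainlinkError):
    """Invalid configuration value (validation failure before any work)."""


class MalformedTrajectoryError(DomainlinkError):
    """Trajectory models disagree in atom count or ordering."""


class PdbParseError(DomainlinkError):
    """A fixed-column coordinate field could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class NumberingOverflowError(DomainlinkError):
    """Residue or atom numbering exceeds the fixed-column format limit."""


class EmptySelectionError(DomainlinkError):
    """An atom selection matched nothing; always a mistake in this pipeline."""


class DegenerateSuperpositionError(DomainlinkError):
    """Fewer than 3 atoms, or a collinear/degenerate point configuration."""


class DegenerateSeriesError(DomainlinkError):
    """A vector series is constant: its distance variance is zero."""


class ShapeError(DomainlinkError):
    """Array shapes or frame counts are inconsistent."""


class LabelError(DomainlinkError):
    """Domain label sets or orderings disagree."""


class UnknownResidueError(DomainlinkError):
    """A sequence letter is not one of the 20 standard amino acids."""


class UnknownElementError(DomainlinkError):
    """An element (or labeled-isotope) symbol is not in the mass table."""


class ChargeError(DomainlinkError):
    """Charge state must be a positive integer."""


class NoCysteineError(DomainlinkError):
    """A disulfide operation requires at least one unmodified cysteine."""


class SiteAmbiguityError(DomainlinkError):
    """Quantification requires exactly one targetable cysteine."""


class ModificationError(DomainlinkError):
    """A modification is unknown or placed on an invalid position."""


class EmptyInputError(DomainlinkError):
    """An input container (peak list) is empty."""


class NoSignalError(DomainlinkError):
    """Neither fit component received any weight; nothing to quantify."""
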