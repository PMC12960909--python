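"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`EvoClockError` so the CLI can map
failures to a categorized message and a nonzero exit status.
"""


class EvoClockError(Exception):
    """Base class for all evoclock errors."""


class FormatError(EvoClockError):
    """Malformed input file (e.g. FASTA not starting with a header)."""


class ValidationError(EvoClockError):
    """Input violates a dataset invariant (e.g. duplicate sequence ids)."""


class ConfigurationError(EvoClockError):
    """Invalid run configuration (missing column, unknown category, ...)."""


class EmptyDatasetError(EvoClockError):
    """No samples remain after joining or filtering."""


class InsufficientDataError(EvoClockError):
    """Too few usable data points for the requested statistical operation."""


class DegenerateInputError(EvoClockError):
    """Input is structurally unable to constrain the fit (e.g. all t == 0)."""


class AlignerError(EvoClockError):
    """External aligner missing or produced malformed output."""
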