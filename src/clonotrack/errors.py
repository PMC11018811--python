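"""Exception hierarchy for clonotrack.

Every error raised by the library derives from :class:`ClonotrackError`
so callers can catch the whole family with one clause.
"""


class ClonotrackError(Exception):
    """Base class for all clonotrack errors."""


class FormatError(ClonotrackError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class EmptyTableError(ClonotrackError):
    """An operation received or produced a repertoire with no records."""


class ChainMismatchError(ClonotrackError):
    """TRA and TRB tables were mixed where a single locus is required."""


class DepthError(ClonotrackError):
    """A requested downsampling depth exceeds the available molecule count."""


class UndefinedStatisticError(ClonotrackError):
    """A statistic is undefined for the given input (empty table, no hits...)."""


class NoHitsError(UndefinedStatisticError):
    """A query set shares no clonotype with the ranked reference."""


class ConfigError(ClonotrackError):
    """Invalid configuration or parameter value."""
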