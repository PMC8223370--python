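"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`CytodynaError`, so callers can catch the package's failures without
also swallowing bugs.
"""


class CytodynaError(Exception):
    """Base class for all cytodyna errors."""


class SchemaError(CytodynaError, ValueError):
    """Input table is missing a required column or has a malformed header."""


class IntegrityError(CytodynaError, ValueError):
    """Input table violates a uniqueness or terminal-sampling invariant."""


class PanelMembershipError(CytodynaError, ValueError):
    """A mediator name is not part of the declared panel."""


class DesignError(CytodynaError, ValueError):
    """A synthetic-cohort design is internally inconsistent (e.g. non-PSD)."""


class ConfigurationError(CytodynaError, ValueError):
    """Required groups (baseline, interval endpoints) are absent from the data."""


class InsufficientDataError(CytodynaError, ValueError):
    """Too few observations to compute the requested statistic."""


class UndefinedCorrelationError(CytodynaError, ValueError):
    """Correlation is undefined (constant input after any ranking)."""


class UsageError(CytodynaError, ValueError):
    """Operation called with incompatible arguments (mixed strains, bad format)."""
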