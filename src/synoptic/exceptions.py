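"""Exception hierarchy for the synoptic package.

Every error raised by the library derives from :class:`SynopticError` so that
pipeline code can distinguish data/model problems from programming errors.
"""


class SynopticError(Exception):
    """Base class for all synoptic errors."""


class SchemaError(SynopticError):
    """A required column is missing from an input table."""


class ValidationError(SynopticError):
    """A row or record violates a data-model invariant."""


class DuplicateMeasurementError(ValidationError):
    """The same (site, season, solute) measurement appears more than once."""


class TopologyError(ValidationError):
    """The site edge list is not a single rooted tree (cycle, multiple roots...)."""


class NestingError(TopologyError):
    """A site's drainage area exceeds that of its downstream site, or the
    children of a site together drain more area than the site itself."""


class ZeroVarianceError(SynopticError):
    """Concentrations are constant, so scaling / correlation is undefined."""


class InsufficientDataError(SynopticError):
    """Too few sites or pairs for the requested statistic."""


class MissingOutletError(SynopticError):
    """The outlet concentration needed for leverage is absent or zero."""


class UndefinedCorrelationError(SynopticError):
    """Rank correlation undefined (zero variance in one season)."""


class ConfigError(SynopticError):
    """An invalid simulation or run configuration."""
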