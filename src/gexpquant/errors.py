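"""Exception hierarchy for gexpquant.

Grouped so the CLI can map error families onto distinct exit codes:
usage/configuration problems, data/format problems, and degenerate fits.
"""


class GexpError(Exception):
    """Base class for all gexpquant errors."""


class InvalidParameterError(GexpError, ValueError):
    """A numeric parameter violates its physical or statistical constraints."""


class ConfigurationError(GexpError, ValueError):
    """A configuration value is inconsistent (e.g. matching tolerance too wide)."""


class FragmentTableError(GexpError, ValueError):
    """A fragment table file cannot be parsed (missing column, empty file...)."""


class AmbiguousAssignmentError(GexpError, ValueError):
    """Two panel genes claim the same electrophoresis fragment."""


class NormalizationError(GexpError, ValueError):
    """The spike-in fragment is missing or has zero area; the run is unusable."""


class DegenerateFitError(GexpError, ValueError):
    """A regression cannot be fitted (too few points, identical abscissae...)."""


class UnknownGeneError(GexpError, KeyError):
    """A gene is absent from the calibration model."""


class EmptySummaryError(GexpError, ValueError):
    """No usable data remain after exclusions (e.g. all pairs below limit)."""
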