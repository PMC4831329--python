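"""Exception hierarchy for lungsim.

All lungsim-specific failures derive from :class:`LungSimError` so callers can
catch the package's errors with a single except clause. Subclasses also derive
from the closest builtin (ValueError/KeyError) so generic handling keeps working.
"""


class LungSimError(Exception):
    """Base class for all lungsim errors."""


class FormatError(LungSimError, ValueError):
    """A file or table does not have the expected layout (missing columns, ...)."""


class ValidationError(LungSimError, ValueError):
    """Data are syntactically fine but violate a model invariant."""


class InfeasibleTreeError(ValidationError):
    """Per-generation branch/terminal counts cannot be realised as a binary tree."""


class DomainError(LungSimError, ValueError):
    """A numeric argument is outside its physical domain (negative length, ...)."""


class LookupIdError(LungSimError, KeyError):
    """An id (branch, region) does not exist in the addressed container."""


class GridMismatchError(LungSimError, ValueError):
    """Two voxel grids or masks that must agree in shape do not."""


class DegenerateClusteringError(LungSimError, ValueError):
    """Fewer distinct intensities than requested clusters."""


class DegenerateFiducialsError(LungSimError, ValueError):
    """Fiducial configuration is rank-deficient (collinear or coincident points)."""


class ConfigurationError(LungSimError, ValueError):
    """Inconsistent or incomplete runtime configuration."""


class MetricError(LungSimError, ValueError):
    """A required frequency or column is missing when deriving summary metrics."""


class PhantomSpecError(LungSimError, ValueError):
    """A phantom specification cannot be realised (e.g. defect target too large)."""
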