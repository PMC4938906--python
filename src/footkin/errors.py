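"""Exception hierarchy for footkin."""


class FootkinError(Exception):
    """Base class for all footkin errors."""


class TemplateError(FootkinError):
    """Invalid kinematic template (tree structure, joint inventory, schema)."""


class DimensionError(FootkinError, ValueError):
    """Vector/matrix dimensions do not match the expected layout."""


class ConfigurationError(FootkinError):
    """Incomplete or inconsistent rhythm / solver configuration."""


class ConstraintConflictError(FootkinError):
    """Rhythm couplings are mutually inconsistent (rank-deficient or cyclic)."""


class FitError(FootkinError):
    """Degenerate input to a least-squares fit (ellipsoid, TPS)."""


class ScalingError(FootkinError):
    """Template scaling failed (e.g. non-invertible warp Jacobian)."""


class InsufficientDataError(FootkinError):
    """Too few visible markers to pose the frame."""


class TrialError(FootkinError):
    """Every frame of a trial failed to solve."""


class GenerationError(FootkinError):
    """Synthetic gait spec violates template joint limits."""


class UndefinedStatisticError(FootkinError):
    """Statistic is undefined for this input (e.g. COV25 with zero RoM)."""


class NumericError(FootkinError):
    """A numerical routine failed to converge."""
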