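"""Exception hierarchy for the localization pipeline."""


class HooplocError(Exception):
    """Base class for all package-specific errors."""


class InsufficientCorrespondencesError(HooplocError):
    """Fewer than the six world/image point pairs needed for the 11-parameter DLT."""


class DegenerateGeometryError(HooplocError):
    """Numerically rank-deficient or ill-conditioned linear system (e.g. coplanar
    calibration points, near-parallel triangulation rays, singular fixed-height solve)."""


class InsufficientViewsError(HooplocError):
    """Triangulation requested with fewer than two distinct camera views."""


class DegenerateProjectionError(HooplocError):
    """Projection denominator too close to zero (point at/behind the camera plane)."""


class InsufficientHistoryError(HooplocError):
    """Frame stream shorter than the background-model burn-in period."""


class DegenerateTrainingError(HooplocError):
    """Classifier training requested with a single class present."""


class UndefinedRateError(HooplocError):
    """Evaluation rate requested with an empty/zero denominator."""


class PackingError(HooplocError):
    """Requested minimum player separation infeasible for the court and count."""


class SchemaError(HooplocError):
    """Malformed camera / detection / configuration file."""


class ProblemSizeError(HooplocError):
    """Exhaustive assignment oracle invoked above its instance-size guard."""
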