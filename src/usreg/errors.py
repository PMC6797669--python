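"""Exception hierarchy shared across the package."""


class UsregError(Exception):
    """Base class for all package errors."""


class FormatError(UsregError):
    """A file could not be parsed in the declared format."""


class GeometryError(UsregError):
    """Invalid or mismatched voxel-grid geometry."""


class ParseError(UsregError):
    """A text record (e.g. a landmark row) could not be parsed."""


class CorrespondenceError(UsregError):
    """Paired landmark sets do not define a one-to-one correspondence."""


class CapacityError(UsregError):
    """More samples requested than the support can provide."""


class CoverageError(UsregError):
    """A motion moves too much of the structure outside the field of view."""


class SizeError(UsregError):
    """Grid too small for the requested operation."""


class TrainingError(UsregError):
    """Optimization of the network diverged."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class OptimizationError(UsregError):
    """Non-finite objective or gradient during registration."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class DegenerateInputError(UsregError):
    """An input (e.g. an empty mask) admits no meaningful solution."""


class UndefinedStatisticError(UsregError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class ChainingError(UsregError):
    """Two case pairs cannot be chained (mismatched middle volume)."""


class PipelineStageError(UsregError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
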