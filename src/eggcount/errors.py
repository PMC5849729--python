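"""Exception hierarchy shared across the pipeline."""


class EggCountError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(EggCountError, ValueError):
    """A precondition on user-supplied input was violated."""


class PlacementError(EggCountError):
    """Synthetic objects could not be placed within the retry budget."""


class PlateNotFoundError(EggCountError):
    """No dark, circular, sufficiently large region was found in the frame."""


class InsufficientDataError(EggCountError):
    """Too few observations to fit or evaluate (e.g. area partition, correlation)."""


class UnimodalAreaError(EggCountError):
    """The particle-area distribution shows a single mode; no dust/egg valley exists."""

    def __init__(self, message: str, mode: float | None = None):
        super().__init__(message)
        self.mode = mode


class UndefinedCorrelationError(EggCountError):
    """Rank correlation is undefined (zero variance in one of the vectors)."""
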