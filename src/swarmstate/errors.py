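"""Exception hierarchy for the swarmstate package."""


class SwarmError(Exception):
    """Base class for all swarmstate errors."""


class TrajectoryFormatError(SwarmError):
    """Trajectory file is missing required columns or is otherwise malformed."""


class TrajectoryParseError(SwarmError):
    """A row of a trajectory file could not be parsed (carries the row number)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class InsufficientDataError(SwarmError):
    """Not enough valid frames / samples / bins for the requested computation."""


class DegenerateSeriesError(SwarmError):
    """A series is degenerate (e.g. zero rms) and cannot be normalized."""


class FitConvergenceError(SwarmError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class StabilityError(SwarmError):
    """Integrator time step too large for the configured dynamics."""
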