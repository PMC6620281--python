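"""Exception hierarchy for the LSN pipeline.

Every stage raises a subclass of :class:`LSNError` so the CLI can map
user-facing problems (bad parameters, degenerate inputs) to exit code 1
and internal failures to exit code 2.
"""


class LSNError(Exception):
    """Base class for all package errors."""


class ParameterError(LSNError, ValueError):
    """A configuration or argument value violates its contract."""


class DomainError(LSNError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class GeometryError(LSNError):
    """A contour or segment has a shape the method cannot handle."""


class DegenerateMaskError(LSNError):
    """A segmentation mask is empty or too small to trace."""


class DegeneratePhaseError(LSNError):
    """One of the two intensity phases has (near-)zero membership mass."""


class DivergenceError(LSNError):
    """The level-set evolution produced non-finite values."""

    def __init__(self, message: str, iteration: int | None = None,
                 energy_trace: list | None = None):
        super().__init__(message)
        self.iteration = iteration
        self.energy_trace = energy_trace or []


class InputError(LSNError):
    """An input file is missing, unreadable, or underspecified."""
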