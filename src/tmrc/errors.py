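"""Exception hierarchy.

Configuration problems (bad names, inconsistent shapes, invalid parameter
values) raise :class:`ConfigurationError` / :class:`ValidationError`;
runtime numerical failures (integrator blow-up, reducible kernel graphs,
eigensolver breakdown) raise :class:`NumericalError` subclasses.  The CLI
maps the former to exit code 2 and the latter to exit code 3.
"""


class TmrcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TmrcError):
    """An input name, file or parameter block is not understood."""


class ValidationError(ConfigurationError):
    """A parameter value violates a documented precondition."""


class NumericalError(TmrcError):
    """A numerical procedure failed at run time."""


class IntegrationBlowupError(NumericalError):
    """The SDE integrator produced a non-finite or runaway state.

    Carries the step index at which the blow-up was detected.
    """

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"integration blew up at step {step}")


class DisconnectedGraphError(NumericalError):
    """The diffusion-map kernel graph has isolated points.

    The row-stochastic matrix would be reducible and the diffusion map
    meaningless; the offending point indices are reported.
    """

    def __init__(self, isolated, message: str | None = None):
        self.isolated = list(isolated)
        super().__init__(
            message
            or "kernel graph has isolated points (increase sigma, the cutoff "
            f"radius, or the burst size): indices {self.isolated[:20]}"
        )


class DegenerateCoordinateError(NumericalError):
    """All reaction-coordinate values coincide; binning is impossible."""
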