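"""Exception hierarchy shared across the pipeline stages."""


class PensonarError(Exception):
    """Base class for all package errors."""


class EmptyWindowError(PensonarError):
    """No sonar revolution lies fully inside the requested phase window.

    Carries the window and the number of candidate frames inspected so a
    pipeline run can log the exclusion with context.
    """

    def __init__(self, window, n_candidates):
        self.window = tuple(window)
        self.n_candidates = int(n_candidates)
        super().__init__(
            f"no frame fully inside window [{window[0]}, {window[1]}) "
            f"({n_candidates} candidate frames inspected)"
        )


class NotMeasurableError(PensonarError):
    """A distance was requested from an image with category 'invalid'."""


class ConfigurationError(PensonarError):
    """A backend or run configuration is inconsistent or unavailable."""


class DegenerateDesignError(PensonarError):
    """The factorial layout cannot support the requested partition."""


class DegenerateTestError(PensonarError):
    """A pseudo-F test has no usable denominator or too few observations."""


class PipelineError(PensonarError):
    """An end-to-end run produced no usable measurements."""
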