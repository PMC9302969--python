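"""Exception types shared across the package."""


class QlinError(Exception):
    """Base class for package errors."""


class DegenerateModelError(QlinError, ValueError):
    """The model transfer function is identically zero / has no defined phase."""


class ConfigurationError(QlinError, ValueError):
    """A required configuration field (e.g. the impedance scale) is missing."""


class InsufficientDataError(QlinError, ValueError):
    """Not enough usable data (spikes, trials, points) for the requested analysis."""


class FitFailureError(QlinError, RuntimeError):
    """Least-squares fitting did not converge to a usable optimum."""


class UndefinedPhaseError(QlinError, ValueError):
    """Phase estimation attempted on an all-zero (or otherwise degenerate) response."""


class UndefinedRatioError(QlinError, ValueError):
    """Paired-pulse ratio requested but the first response is below the noise floor."""
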