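"""Exception hierarchy shared by all microbeam modules."""


class MicrobeamError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MicrobeamError, ValueError):
    """An argument lies outside the physical domain of a formula."""


class ValidationError(MicrobeamError, ValueError):
    """Structured input (centerline, cohort row, config) fails its contract."""


class InsufficientDataError(MicrobeamError, ValueError):
    """An estimator was given too few points to produce a result."""


class NoUndulationError(MicrobeamError, ValueError):
    """A centerline carries no measurable periodic undulation.

    Raised by the wavelength estimators for flat or monotone signals;
    the pipeline treats it as "no wavelength", not as a failure.
    """


class ConfigError(MicrobeamError, ValueError):
    """A run configuration is internally inconsistent."""
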