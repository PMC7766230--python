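"""Exception hierarchy shared across the package."""


class AirseqError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(AirseqError, ValueError):
    """A configuration object violates one of its invariants."""


class FormatError(AirseqError, ValueError):
    """A station CSV (or similar on-disk artifact) violates its contract."""


class CoverageError(AirseqError, ValueError):
    """A requested aggregate has no observations for one of its bins."""


class DegenerateSeriesError(AirseqError, ValueError):
    """A statistic is undefined on the given series (e.g. zero variance)."""


class NotFittedError(AirseqError, RuntimeError):
    """A scaler or model was used before being fitted/trained."""


class TrainingError(AirseqError, RuntimeError):
    """Optimization diverged (non-finite loss)."""
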