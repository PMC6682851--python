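"""Exception hierarchy for screentriage."""


class ScreenTriageError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ScreenTriageError):
    """An input file does not conform to the expected column contract."""


class IntegrityError(ScreenTriageError):
    """Cross-table references are broken (e.g. a reading of an unknown exam)."""


class ValidationError(ScreenTriageError):
    """A record violates a field-level invariant (bounds, labels, duplicates)."""


class ConfigError(ScreenTriageError):
    """A configuration object is internally inconsistent."""


class GenerationError(ScreenTriageError):
    """Synthetic-cohort generation cannot proceed (e.g. exam without a block)."""


class CalibrationError(ScreenTriageError):
    """Score calibration is impossible on the given sample."""


class EstimationError(ScreenTriageError):
    """An ROC/AUC/variance estimate is undefined for the given data."""
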