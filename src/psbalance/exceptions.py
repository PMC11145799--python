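"""Exception hierarchy for psbalance."""


class PsbalanceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PsbalanceError):
    """Invalid configuration (bad probabilities, non-PD correlation, ...)."""


class CalibrationError(PsbalanceError):
    """Intercept calibration could not reach the requested target."""


class EstimationError(PsbalanceError):
    """Model fitting is impossible on the given data (single group, no events, rank deficiency)."""


class StratificationError(PsbalanceError):
    """Fine stratification cannot be built (too few exposed subjects)."""


class PruningError(PsbalanceError):
    """Cross-classification pruning removed every subject."""


class BalanceError(PsbalanceError):
    """A balance metric is undefined (zero-variance covariate, empty group)."""
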