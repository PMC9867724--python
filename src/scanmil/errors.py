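"""Exception hierarchy for scanmil."""


class ScanmilError(Exception):
    """Base class for all scanmil errors."""


class ConfigurationError(ScanmilError):
    """Invalid configuration values (proportions out of range, bad fractions, ...)."""


class ValidationError(ScanmilError):
    """Invalid runtime inputs (empty bags, dimension mismatches, bad labels, ...)."""


class FeatureExtractorUnavailableError(ScanmilError):
    """A requested feature extractor cannot run in this environment."""


class CacheVersionError(ScanmilError):
    """A cached feature artifact does not match the requested extractor/version."""


class DegenerateComparisonError(ScanmilError):
    """A paired AUC comparison has zero variance of the difference."""


class TrainingDivergedError(ScanmilError):
    """Training aborted because the loss became non-finite."""
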