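"""Exception hierarchy shared across the pipeline."""


class MfblupError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MfblupError):
    """Invalid user-supplied configuration (bad thresholds, rates, boundaries)."""


class ValidationError(MfblupError):
    """Inconsistent data (pedigree cycles, non-PSD covariances, mismatched ids)."""


class DataError(MfblupError):
    """Degenerate data encountered at run time (empty matrix after QC,
    undefined Fst denominator, singular design)."""
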