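"""Exception hierarchy shared across the pipeline."""


class EmofusionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmofusionError):
    """Invalid configuration value or block."""


class TimingError(EmofusionError):
    """Degenerate stimulus timing (voice too short for the frame sequence)."""


class SchemaError(EmofusionError):
    """A table is missing required columns or contains unjoinable rows."""


class CompletenessError(EmofusionError):
    """Required per-stimulus or per-subject data are absent."""


class DegenerateRocError(EmofusionError):
    """Only one response class present; no ROC can be formed."""


class FitError(EmofusionError):
    """A model fit failed to converge or had too few informative points."""


class InsufficientDataError(EmofusionError):
    """Fewer complete observations than the analysis requires."""


class InsufficientVarianceError(EmofusionError):
    """A variable is constant where variance is required."""


class CollinearityError(EmofusionError):
    """Covariate design matrix is numerically rank deficient."""
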