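"""Exception hierarchy shared across radvar modules."""


class RadvarError(Exception):
    """Base class for all radvar errors."""


class ConfigurationError(RadvarError):
    """Invalid configuration (bad thresholds, unknown identifiers, ...)."""


class InputError(RadvarError):
    """Malformed or inconsistent input data (shape mismatches, bad tables)."""


class ParseError(InputError):
    """Unparseable record; message names the offending record/sample."""


class VocabularyError(InputError):
    """A consequence term outside the severity vocabulary."""


class DegenerateSetError(RadvarError):
    """A variant set whose test statistic is degenerate (zero variance)."""


class FitError(RadvarError):
    """Null-model fitting failure."""


class PerfectSeparationError(FitError):
    """Logistic fit diverged; a Firth/penalized fallback is advised."""


class EmptyStratumError(RadvarError):
    """A stratum without cases or without controls; callers should skip it."""


class InsufficientDataError(RadvarError):
    """Not enough non-missing observations for the requested statistic."""


class PipelineError(RadvarError):
    """Pipeline stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
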