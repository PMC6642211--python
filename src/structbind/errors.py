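"""Exception hierarchy shared across the package."""


class StructbindError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StructbindError, ValueError):
    """A generator or analysis configuration field is invalid."""


class FormatError(StructbindError, ValueError):
    """An input table or file lacks required columns or is malformed."""


class DegenerateInputError(StructbindError, ValueError):
    """Input is structurally valid but empty/degenerate for the operation."""


class ProfileExcluded(StructbindError):
    """A transcript profile fails a quantifiability rule and is dropped.

    Raised e.g. when all nucleotides of a PARS profile are undetermined, or
    when DMS coverage is below the 10%-of-length threshold.
    """


class GenerationError(StructbindError, RuntimeError):
    """The synthetic generator cannot satisfy its own constraints."""


class FitConvergenceError(StructbindError, RuntimeError):
    """Nonlinear least squares failed to converge; carries the last iterate."""

    def __init__(self, message, alpha=None, beta=None, rss=None, n_iter=None):
        super().__init__(message)
        self.alpha = alpha
        self.beta = beta
        self.rss = rss
        self.n_iter = n_iter
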