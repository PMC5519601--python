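"""Exception hierarchy for envgreml."""


class EnvGremlError(Exception):
    """Base class for all envgreml errors."""


class DimensionError(EnvGremlError):
    """Non-positive or inconsistent dimensions."""


class DomainError(EnvGremlError):
    """Argument outside its mathematical domain (thresholds, proportions, ...)."""


class FormatError(EnvGremlError):
    """Malformed on-disk data (bad magic bytes, duplicate IDs, truncation)."""


class ModelError(EnvGremlError):
    """Statistically invalid model input (non-PSD covariance, rank deficiency)."""


class ConvergenceError(EnvGremlError):
    """Iterative fit failed to converge; carries the likelihood trail."""

    def __init__(self, message, logl_trail=None):
        super().__init__(message)
        self.logl_trail = list(logl_trail) if logl_trail is not None else []


class SelectionError(EnvGremlError):
    """Truncation selection produced an unusable (e.g. empty) subset."""

    def __init__(self, message, realized_proportion=None):
        super().__init__(message)
        self.realized_proportion = realized_proportion


class BoundaryError(EnvGremlError):
    """A variance component is pinned at its floor; dependent quantities undefined."""
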