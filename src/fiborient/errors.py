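"""Exception hierarchy for the fiborient pipeline.

Every stage raises a subclass of :class:`FibOrientError` so callers (and the
command-line front end) can attribute a failure to a pipeline stage.
"""


class FibOrientError(Exception):
    """Base class for all fiborient errors."""


class ImageFormatError(FibOrientError):
    """Unreadable file, unsupported layout, or a multichannel image without
    an explicit channel selection."""


class DegenerateImageError(FibOrientError):
    """Image carries no analyzable structure (all-zero, too small, ...)."""


class ConfigError(FibOrientError):
    """A parameter violates its contract (R, T, B, phantom spec, ...)."""


class ContractError(FibOrientError):
    """An operation was called on an object in the wrong state, e.g. a
    gradient requested on an unnormalized image."""


class EmptyPDFError(FibOrientError):
    """No gradient vectors survived thresholding."""


class FitError(FibOrientError):
    """Nonlinear fit failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
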