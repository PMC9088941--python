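"""Exception hierarchy.

All package-raised errors derive from :class:`QuenchBindError` so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class QuenchBindError(Exception):
    """Base class for all quenchbind errors."""


class ValidationError(QuenchBindError, ValueError):
    """An input object or file violates a documented invariant."""


class ParseError(QuenchBindError, ValueError):
    """A file could not be parsed; the message carries the line number."""


class FitConvergenceError(QuenchBindError, RuntimeError):
    """A nonlinear fit failed to converge.

    The last iterate (an ``lmfit`` result, when available) is attached as
    ``last_result`` so the caller can inspect how far the optimiser got.
    """

    def __init__(self, message: str, last_result=None):
        super().__init__(message)
        self.last_result = last_result


class ConfigError(QuenchBindError, ValueError):
    """A study configuration is incomplete or inconsistent."""


class IndeterminateForceError(QuenchBindError, ValueError):
    """Sign-based force classification is undefined (a zero on a boundary)."""
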