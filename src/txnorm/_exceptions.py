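"""Exception hierarchy shared across the package.

All data-facing errors derive from :class:`TxnormError` so callers (and the
CLI) can map them onto exit codes without inspecting messages.
"""


class TxnormError(Exception):
    """Base class for all txnorm errors."""


class FormatError(TxnormError, ValueError):
    """A file or table violates the expected plain-text format."""


class DegenerateInputError(TxnormError, ValueError):
    """Input is structurally valid but degenerate for the requested method
    (e.g. an all-zero sample, or too few genes surviving trimming)."""


class DomainError(TxnormError, ValueError):
    """A parameter or value lies outside the method's domain
    (e.g. a non-positive scaling factor)."""


class ConvergenceError(TxnormError, RuntimeError):
    """An iterative numeric procedure failed to converge."""
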