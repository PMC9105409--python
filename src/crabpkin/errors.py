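"""Package exception types."""


class CrabpkinError(Exception):
    """Base class for package errors."""


class NonIdentifiableError(CrabpkinError):
    """The data do not constrain the requested parameters."""


class FitConvergenceError(CrabpkinError):
    """A nonlinear fit failed to converge."""


class TableFormatError(CrabpkinError):
    """An input table is malformed."""
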