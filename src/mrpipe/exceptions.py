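"""Exception hierarchy for mrpipe."""


class MrPipeError(Exception):
    """Base class for all mrpipe errors."""


class FormatError(MrPipeError, ValueError):
    """A file does not conform to the expected tabular layout
    (e.g. a mandatory column is missing)."""


class ValidationError(MrPipeError, ValueError):
    """Parsed content violates a domain invariant (bad allele code,
    non-positive standard error, frequency outside [0, 1], ...)."""


class InsufficientInstrumentsError(MrPipeError, ValueError):
    """An estimator was handed fewer instruments than it requires."""


class ConvergenceError(MrPipeError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostics."""
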