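"""Exception hierarchy for condsize."""


class CondsizeError(Exception):
    """Base class for all condsize errors."""


class DomainError(CondsizeError, ValueError):
    """A physical quantity is outside the model's domain of validity."""


class InputError(CondsizeError, ValueError):
    """Malformed or inconsistent user input (files, tables, arguments)."""


class ModelViolationError(CondsizeError, ValueError):
    """Measured data is incompatible with the assumed circuit topology."""


class FitError(CondsizeError, ValueError):
    """A fit could not be performed (degenerate or insufficient data)."""


class InfeasibleMeasurementError(CondsizeError, ValueError):
    """The measured conductance cannot be explained by any admissible lumen."""


class NoSolutionError(CondsizeError, ValueError):
    """The inversion bracket contains no sign change (no admissible root)."""
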