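"""Exception hierarchy shared by all mrsxml modules.

The CLI maps these onto exit codes (validation -> 1, numerics -> 2,
I/O -> 3); library users catch them directly.
"""


class MrsError(Exception):
    """Base class for all mrsxml errors."""


class ParameterError(MrsError, ValueError):
    """An operator or constructor was given an invalid parameter."""


class ValidationError(MrsError, ValueError):
    """A document, config or dataset violates the exchange-format rules."""


class NumericsError(MrsError, ArithmeticError):
    """A numerical procedure cannot produce a meaningful result."""


class DegenerateNoiseError(NumericsError):
    """The designated noise region has zero variance, so SNR is undefined."""
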