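"""Exception hierarchy for the dialflux workbench."""


class DialfluxError(Exception):
    """Base class for all dialflux errors."""


class InvalidInputError(DialfluxError, ValueError):
    """An input violates a type invariant (e.g. nonpositive flow)."""


class UndefinedInputError(DialfluxError, ValueError):
    """A requested quantity is undefined for the given input (e.g. extraction at zero inlet)."""


class InvalidMeasurementError(DialfluxError, ValueError):
    """A measurement value is physically impossible (e.g. negative absorbance)."""


class InsufficientDataError(DialfluxError, ValueError):
    """Too few records to compute the requested statistic."""


class InfeasibleTargetError(DialfluxError, ValueError):
    """A clearance target lies outside the attainable interval for the given flows."""


class UnidentifiableError(DialfluxError, ValueError):
    """The data carry no information about the parameter being fitted."""


class SchemaError(DialfluxError, ValueError):
    """A delimited-text input violates the expected measurement schema."""
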