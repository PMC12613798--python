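"""Exception hierarchy shared across the package."""


class ThermoTKError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ThermoTKError, ValueError):
    """A value violates a domain invariant (non-positive rate, mass, temperature...)."""


class SchemaError(ThermoTKError, ValueError):
    """An input table does not match the expected column schema."""


class UnfittableError(ThermoTKError, ValueError):
    """A regression cannot be fitted (too few records, zero predictor variance...)."""


class EstimationError(ThermoTKError, ValueError):
    """A toxicokinetic time-series fit cannot be attempted."""


class PipelineError(ThermoTKError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
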