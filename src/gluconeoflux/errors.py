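"""Exception hierarchy for gluconeoflux."""


class GluconeofluxError(Exception):
    """Base class for all package errors."""


class ModelParseError(GluconeofluxError):
    """Model file could not be parsed; message carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CarbonBalanceError(GluconeofluxError):
    """An atom transition does not conserve carbon."""


class ConfigurationError(GluconeofluxError):
    """A required coefficient table or tag is missing or inconsistent."""


class DegenerateFluxError(GluconeofluxError):
    """A live EMU has zero total influx under the supplied fluxes."""


class UnitError(GluconeofluxError):
    """Fluxes supplied on the wrong scale (normalized vs absolute)."""


class FitError(GluconeofluxError):
    """Flux estimation failed to produce any converged start."""


class InfeasibleError(GluconeofluxError):
    """No feasible flux vector exists under the stated constraints."""
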