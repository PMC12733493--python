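"""Exception hierarchy for the rismhydra package."""


class RismHydraError(Exception):
    """Base class for all package errors."""


class InvalidModelError(RismHydraError):
    """A solvent or solute model violates its invariants."""


class ConvergenceError(RismHydraError):
    """An iterative solve failed to reach the residual tolerance.

    Carries the last residual and, where available, the residual trace.
    """

    def __init__(self, message, residual=None, trace=None):
        super().__init__(message)
        self.residual = residual
        self.trace = list(trace) if trace is not None else []


class ParseError(RismHydraError):
    """A structural or parameter file could not be parsed."""

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class MissingParameterError(RismHydraError):
    """A (residue, atom) key was absent from the parameter table."""


class GridSizeError(RismHydraError):
    """A requested 3D grid exceeds the configured memory ceiling."""

    def __init__(self, message, required_bytes=None):
        super().__init__(message)
        self.required_bytes = required_bytes


class NoBoundaryError(RismHydraError):
    """The shell-density profile has no first-minimum hydration boundary."""


class FixtureError(RismHydraError):
    """A synthetic-fixture recipe is unsatisfiable."""


class ConfigError(RismHydraError):
    """A pipeline configuration failed schema validation."""
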