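"""Exception hierarchy for rampclamp."""


class RampclampError(Exception):
    """Base class for all package-specific errors."""


class InputError(RampclampError, ValueError):
    """Invalid argument or malformed domain object."""


class FormatError(RampclampError, ValueError):
    """Malformed recording / config file."""


class ConfigError(RampclampError, ValueError):
    """Invalid run configuration (schema violation)."""


class SimulationError(RampclampError, RuntimeError):
    """Integrator failure during a protocol simulation."""


class EstimationError(RampclampError, RuntimeError):
    """A fit/estimate could not be computed from the data given."""


class InconsistencyError(RampclampError, RuntimeError):
    """Mutually inconsistent analysis results (e.g. spikes without a block current)."""
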