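"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Invalid configuration or parameter range."""


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class SimulationError(RuntimeError):
    """Simulation could not satisfy its sampling targets."""
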