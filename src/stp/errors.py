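"""Exception types used across the package."""


class ContractError(ValueError):
    """An operation was called with arguments violating its contract."""


class InvalidParameterError(ContractError):
    """A neuron or layer parameter is outside its valid domain."""


class ConfigError(ValueError):
    """A configuration file or mode id is invalid."""


class PlanError(ValueError):
    """A network plan is internally inconsistent or unsupported."""


class GraphError(ValueError):
    """A stateful computational graph failed validation or execution."""


class StaleStateError(RuntimeError):
    """Neuron state from a previous sample was not reset before reuse."""
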