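"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid hyperparameter or configuration value."""


class ContractError(ValueError):
    """An input violates an operation's precondition (shape, dtype, range)."""
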