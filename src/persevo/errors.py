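"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter or input lies outside its documented domain."""


class ContractViolationError(RuntimeError):
    """An operation was called outside its precondition (e.g. the killing
    branch of the pharmacodynamic function invoked at a sub-MIC dose)."""


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


class ExtinctPopulationError(ValueError):
    """An analysis that is undefined for extinct populations received one."""
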