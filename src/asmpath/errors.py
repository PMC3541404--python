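"""Exception hierarchy shared across the package."""


class AsmPathError(Exception):
    """Base class for all package errors."""


class FormatError(AsmPathError, ValueError):
    """An input file violates its declared format."""


class ConfigError(AsmPathError, ValueError):
    """A configuration object is invalid or infeasible."""


class ContractError(AsmPathError, ValueError):
    """A caller violated an operation precondition."""
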