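"""Exception hierarchy shared across the pipeline."""


class ConnectomlError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ConnectomlError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ContractError(ConnectomlError, ValueError):
    """An input violates an operation's documented contract."""


class DegenerateInputError(ConnectomlError, ValueError):
    """Data too degenerate to process (zero variance, constant series, ...)."""


class GenerationError(ConnectomlError, RuntimeError):
    """Synthetic-data generation could not satisfy its own invariants."""
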