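"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class FFMError(Exception):
    """Base class for all ffmkit errors."""


class ConfigError(FFMError):
    """Invalid configuration, parameters or schema."""


class DataError(FFMError):
    """Invalid, inconsistent or missing input data (meshes, labels, tables)."""


class NumericalError(FFMError):
    """A numerical procedure failed or its result is undefined."""
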