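"""Exception hierarchy shared by the library and the CLI.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class MicroexprError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MicroexprError):
    """Invalid or unknown configuration (bad keys, missing label table...)."""


class DataError(MicroexprError):
    """Problem with input data (unreadable image, empty clip, bad shape)."""


class LabelError(DataError):
    """Unknown emotion label for a dataset vocabulary."""


class ProtocolError(DataError):
    """Evaluation protocol cannot be applied (e.g. a single subject)."""


class NumericalError(MicroexprError):
    """Numerical failure during optimisation (NaN/Inf loss)."""
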