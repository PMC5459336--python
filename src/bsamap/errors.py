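"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and its
subclasses) -> 3, NumericalError -> 4.
"""


class BsamapError(Exception):
    """Base class for all package errors."""


class ConfigError(BsamapError):
    """Invalid or incomplete configuration."""


class DataError(BsamapError):
    """Invalid, missing, or inconsistent input data."""


class GridMismatchError(DataError):
    """Two volumes do not share the same voxel grid."""


class NumericalError(BsamapError):
    """A numerical procedure failed (e.g. ICA non-convergence)."""
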