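"""Exception hierarchy for netcbp.

Every error raised by the library derives from :class:`NetCBPError`, so CLI
and pipeline code can catch one type and turn it into a diagnostic.
"""


class NetCBPError(Exception):
    """Base class for all netcbp errors."""


class MatrixFormatError(NetCBPError):
    """Input file violates the expected labeled-matrix layout."""


class MatrixParseError(NetCBPError):
    """A cell could not be parsed as a number; message names row/column."""


class MatrixValueError(NetCBPError):
    """A value is outside its permitted domain (e.g. interaction not 0/1)."""


class DatasetConsistencyError(NetCBPError):
    """Identifier sets of the three matrices cannot be aligned."""


class DegenerateNetworkError(NetCBPError):
    """A similarity network cannot be normalized (zero row sum)."""


class ConvergenceError(NetCBPError):
    """Fixed-point propagation failed to reach tolerance within max_iter."""


class UnknownEntityError(NetCBPError):
    """A queried drug or protein identifier is not in the dataset."""


class DegenerateTrainingError(NetCBPError):
    """Training data too small/degenerate for the requested procedure."""
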