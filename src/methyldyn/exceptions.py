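"""Exception hierarchy used across the package."""


class MethylDynError(Exception):
    """Base class for all methyldyn errors."""


class TableFormatError(MethylDynError):
    """A tabular input file is malformed (missing columns, bad rows)."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        #: list of (line_number, detail) tuples for offending rows
        self.rows = rows or []


class InsufficientDataError(MethylDynError):
    """Too few usable observations for the requested computation."""


class ConvergenceError(MethylDynError):
    """A nonlinear fit failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PairingError(MethylDynError):
    """No probes could be matched between two datasets."""
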