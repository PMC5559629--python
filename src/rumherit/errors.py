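"""Exception hierarchy shared across the package.

The pipeline CLI maps these onto exit codes (config 2, data format 3,
numerical 4), so stage code should raise the most specific class that fits.
"""


class RumheritError(Exception):
    """Base class for all package errors."""


class ConfigError(RumheritError):
    """Invalid configuration, thresholds out of range, infeasible designs."""


class FormatError(RumheritError):
    """Malformed input file (PED/MAP, GRM triangle, FASTA, TSV)."""


class InputError(RumheritError):
    """Structurally valid input that violates an operation's precondition."""


class DegenerateDataError(RumheritError):
    """Data that makes the requested computation meaningless (e.g. a
    constant phenotype, all individuals removed by QC)."""


class NumericalError(RumheritError):
    """Numerical failure beyond repair tolerances (non-PSD kernel, failed
    eigendecomposition)."""
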