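"""Exception hierarchy.

Data/format problems (bad files, broken invariants) and parameter problems
(invalid thresholds) are kept distinct so the CLI can map them to different
exit codes.
"""


class MethporeError(Exception):
    """Base class for all package errors."""


class FormatError(MethporeError):
    """A file violates its format contract (bad header, bad row, inconsistency)."""


class DataError(MethporeError):
    """Inputs are well-formed but violate an analysis precondition."""


class ParameterError(MethporeError):
    """A configuration value is outside its valid range."""


class UndefinedStatisticError(MethporeError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
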