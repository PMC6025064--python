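"""Exception hierarchy shared across the package.

Validation problems (bad files, out-of-range values, broken invariants)
and numerical failures (solver breakdown, singular systems) are kept
distinct so the command-line layer can map them to stable exit codes.
"""


class TDOLError(Exception):
    """Base class for all package errors."""


class ValidationError(TDOLError, ValueError):
    """Input data or domain-object invariant violated."""


class NumericalError(TDOLError, RuntimeError):
    """An optimisation or linear-algebra step failed."""
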