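"""Exception hierarchy.

``UserInputError`` marks problems a user can fix (bad files, unknown
population labels, out-of-range parameters); everything else is treated as an
internal error by the CLI.
"""


class SnpdemogError(Exception):
    """Base class for all package errors."""


class UserInputError(SnpdemogError):
    """Invalid input files, labels or parameter values."""


class ParseError(UserInputError):
    """Malformed input file; message names the offending line."""


class UndefinedLDError(SnpdemogError):
    """LD is undefined for this locus pair (monomorphic margin or too few
    informative samples)."""
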