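"""Exception hierarchy for gazemem.

The CLI maps these onto exit codes: configuration/format problems exit
with 1, data-content problems with 2.
"""


class GazeMemError(Exception):
    """Base class for all gazemem errors."""


class FormatError(GazeMemError):
    """A file or config does not have the expected structure (missing
    columns, unknown feature-set name, bad spec)."""


class ParseError(GazeMemError):
    """A cell in an input file could not be converted to a number."""


class DataError(GazeMemError):
    """Input values violate an invariant (non-monotone timestamps,
    mismatched lengths, too little data for an operation)."""
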