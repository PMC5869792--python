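"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: input/structural problems exit with 2,
numerical failures with 3.
"""


class HmtreeError(Exception):
    """Base class for all package errors."""


class StructuralError(HmtreeError):
    """The input graph violates a structural requirement (cycle, root count,
    or a failed union-reconstruction during the tree transformation)."""


class InputError(HmtreeError):
    """Malformed or inconsistent user input (files, indices, thresholds)."""


class ParameterError(HmtreeError):
    """A model parameter is outside its admissible range."""


class NumericalError(HmtreeError):
    """A recursion or optimization produced a non-finite or impossible
    intermediate quantity."""
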