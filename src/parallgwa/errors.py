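"""Exception hierarchy shared by all modules.

``ParameterError`` covers invalid user-supplied parameters (probabilities
out of range, more processors than work items, ...); ``DataFormatError``
covers malformed input files and violated data invariants. The CLI maps
these to distinct exit codes.
"""


class ParallGWAError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(ParallGWAError, ValueError):
    """An argument value is outside its documented domain."""


class DataFormatError(ParallGWAError, ValueError):
    """An input file or data structure violates the expected format."""


class EmptyDataError(DataFormatError):
    """An input contained no usable records."""


class MergeError(ParallGWAError, RuntimeError):
    """Merging partial results failed (missing or failed tasks)."""


class ConsistencyError(MergeError):
    """Symmetric duplicate blocks disagree beyond tolerance (worker bug)."""
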