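"""Exception hierarchy shared across the package."""


class VernalthermError(Exception):
    """Base class for all package errors."""


class ContractError(VernalthermError):
    """A precondition of an operation was violated by the caller."""


class FormatError(VernalthermError):
    """An input file could not be parsed; the message names the offending row."""


class EmptyInputError(VernalthermError):
    """An input file or collection was empty where data is required."""


class InsufficientDataError(VernalthermError):
    """Not enough valid data to compute the requested summary."""


class NoOptimumError(VernalthermError):
    """All candidate cells are DNF-dominated; no optimum temperature exists."""


class NoRangeError(VernalthermError):
    """No cell shows a positive vernalization effect; no effective range exists."""
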