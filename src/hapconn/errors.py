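"""Exception hierarchy.

``HapconnError`` is the base for all data-level errors so that callers (and
the CLI) can distinguish bad input from programming errors.
"""


class HapconnError(Exception):
    """Base class for all hapconn data errors."""


class InputError(HapconnError, ValueError):
    """Malformed or inconsistent user input (labels, subsets, parameters)."""


class ValidationError(HapconnError, ValueError):
    """A distance matrix or phylogeny violates a structural invariant."""


class CapacityError(HapconnError):
    """An exact computation was requested above the configured size cap."""


class FormatError(HapconnError, ValueError):
    """A file could not be parsed in any supported dialect."""
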