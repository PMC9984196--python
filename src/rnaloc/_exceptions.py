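"""Exception hierarchy.

``RnalocError`` is the base for everything the package raises on purpose;
the CLI maps it to exit code 1 (user error) and anything else to 2.
"""


class RnalocError(Exception):
    """Base class for rnaloc errors."""


class ConfigurationError(RnalocError, ValueError):
    """A simulation or run configuration violates its invariants."""


class InputError(RnalocError, ValueError):
    """An input table, sequence, or annotation violates its schema."""
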