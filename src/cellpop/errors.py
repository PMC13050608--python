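"""Exception hierarchy shared across the package.

``ParseError`` and ``ConfigError`` are distinguished so the command-line
interface can map them to distinct exit codes.
"""


class CellpopError(Exception):
    """Base class for all errors raised by cellpop."""


class ValidationError(CellpopError, ValueError):
    """An in-memory object or operation precondition was violated."""


class ParseError(CellpopError, ValueError):
    """An on-disk input could not be parsed."""


class ConfigError(CellpopError, ValueError):
    """A view configuration violates the config schema."""
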