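"""Exception hierarchy.

Every error raised on purpose by the package derives from :class:`MwSuMDError`
so callers (and the CLI) can distinguish operational failures from bugs.
"""


class MwSuMDError(Exception):
    """Base class for all package errors."""


class FormatError(MwSuMDError):
    """A structure or trajectory file violates its format."""


class EmptyInputError(MwSuMDError):
    """A file or container that must hold at least one record holds none."""


class SelectionError(MwSuMDError):
    """An atom selection expression failed or selected nothing."""


class SelectionParseError(SelectionError):
    """Syntax error in a selection expression; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class CongruenceError(MwSuMDError):
    """Array shapes or atom counts do not match between related objects."""


class DegenerateFitError(MwSuMDError):
    """A least-squares fit (line or rigid superposition) has no unique solution."""


class InsufficientSamplesError(MwSuMDError):
    """A metric series has too few samples for the requested operation."""


class PropagationError(MwSuMDError):
    """The integrator encountered a non-finite force or invalid state."""


class AdapterError(MwSuMDError):
    """An external-engine adapter produced missing or corrupt output."""


class ConfigError(MwSuMDError):
    """A protocol / benchmark / analysis configuration is invalid.

    ``path`` is a dotted field path into the offending document.
    """

    def __init__(self, message: str, path: str = ""):
        super().__init__(f"{path}: {message}" if path else message)
        self.path = path
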