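"""Exception hierarchy.

All errors raised by junctura derive from :class:`JuncturaError` so callers
can catch the package's failures with one except clause.
"""


class JuncturaError(Exception):
    """Base class for all junctura errors."""


class ValidationError(JuncturaError):
    """An input object violates a documented invariant."""


class ConfigurationError(JuncturaError):
    """Parameters are inconsistent or impossible to satisfy."""


class GenerationError(JuncturaError):
    """Constrained random generation exhausted its retry budget."""


class AlignmentError(JuncturaError):
    """A junction read cannot be aligned to its reference flanks."""


class NonLinearArchitectureError(ValidationError):
    """Junctions describe a branched or cyclic structure, not a single path.

    Carries the offending junction ids in :attr:`junction_ids`.
    """

    def __init__(self, message: str, junction_ids=()):
        super().__init__(message)
        self.junction_ids = tuple(junction_ids)


class ParseError(JuncturaError):
    """A file could not be parsed; names the line where possible."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
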