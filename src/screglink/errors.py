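"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation/structural/parse errors exit
with code 1, I/O errors with code 2.
"""


class ScreglinkError(Exception):
    """Base class for all package errors."""


class ValidationError(ScreglinkError):
    """An input violates a documented invariant (bad values, bad parameters)."""


class StructuralError(ValidationError):
    """Shapes, lengths or orderings of inputs do not agree."""


class ParseError(ScreglinkError):
    """A text input could not be parsed; carries the offending fragment."""

    def __init__(self, message: str, raw: str | None = None, line: int | None = None):
        self.raw = raw
        self.line = line
        loc = f" (line {line})" if line is not None else ""
        frag = f": {raw!r}" if raw is not None else ""
        super().__init__(f"{message}{loc}{frag}")
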