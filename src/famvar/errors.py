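"""Exception hierarchy shared across the package."""


class FamvarError(Exception):
    """Base class for all package errors."""


class ValidationError(FamvarError):
    """Invalid user input or configuration (CLI exit code 2)."""


class PedigreeError(ValidationError):
    """Structurally invalid pedigree (cycles, dangling parents, duplicates)."""


class FormatError(ValidationError):
    """Malformed input file.  Carries a line number when one is known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class StageFailure(FamvarError):
    """A pipeline stage produced a result violating its contract (exit code 3)."""
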