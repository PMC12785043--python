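"""Exception hierarchy for thermogram processing errors."""


class ThermogramError(Exception):
    """Base class for all tlbtools errors."""


class FormatError(ThermogramError):
    """Input file has no recognizable thermogram column structure."""


class ParseError(ThermogramError):
    """A cell that should be numeric could not be parsed."""


class UnprocessableProfileError(ThermogramError):
    """Profile is loadable but too short / malformed for the algorithms."""

    def __init__(self, message: str, sample_id: str | None = None):
        self.sample_id = sample_id
        if sample_id is not None:
            message = f"[{sample_id}] {message}"
        super().__init__(message)


class GridMismatchError(ThermogramError):
    """Gridded profiles passed together do not share one temperature grid."""
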