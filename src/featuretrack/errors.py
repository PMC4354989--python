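"""Exception hierarchy shared across the package."""


class FeatureTrackError(Exception):
    """Base class for all featuretrack errors."""


class ParseError(FeatureTrackError):
    """Input text is not syntactically valid in the expected dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(FeatureTrackError):
    """A syntactically valid document violates the dialect schema.

    ``path`` is a JSON-path-like locator such as ``rows[0].annotations[1].start``.
    """

    def __init__(self, message: str, path: str = "$"):
        self.path = path
        super().__init__(f"{path}: {message}")


class ValidationError(FeatureTrackError):
    """A structurally valid document violates a coordinate invariant."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "; ".join(str(v) for v in self.violations) or "invalid viewer"
        )


class AlignmentError(FeatureTrackError):
    """Viewers on one page do not share a sequence length."""

    def __init__(self, lengths):
        self.lengths = list(lengths)
        super().__init__(
            "viewers on one page must share a sequence length, got "
            + ", ".join(str(x) for x in self.lengths)
        )


class ParameterError(FeatureTrackError):
    """An out-of-range or infeasible user parameter."""
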