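"""Exception hierarchy shared across the package."""


class MriraError(Exception):
    """Base class for all package-specific errors."""


class StandoffParseError(MriraError):
    """A standoff line could not be parsed (wrong shape, unknown prefix)."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class OffsetError(MriraError):
    """A character offset falls outside the document or spans are malformed."""


class IntegrityError(MriraError):
    """Referential integrity violated: dangling reference, duplicate id,
    or stored surface text disagreeing with the document text."""


class ScoringError(MriraError):
    """Invalid input to the agreement engine (e.g. texts differ, bad counts)."""


class ConfigError(MriraError):
    """Invalid generator / perturbation / CLI configuration."""
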