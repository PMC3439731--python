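"""Exception hierarchy shared across the pipeline stages."""


class PhyleticError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhyleticError):
    """A file could not be parsed as the expected external format."""


class IntegrityError(PhyleticError):
    """Inputs are well-formed but mutually inconsistent (e.g. a hit
    referencing a gene-model ID that is not part of the run)."""


class ConfigError(PhyleticError):
    """The run configuration is missing, malformed, or self-contradictory."""


class QuerySyntaxError(PhyleticError):
    """A phyletic-pattern expression failed to parse.

    Carries the 0-based character position of the offending token.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position
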