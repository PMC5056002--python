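"""Exception types shared across the pipeline."""


class CrosspathError(ValueError):
    """Base class for all crosspath errors."""


class FormatError(CrosspathError):
    """A file violates its declared format (bad line, duplicate id, ...)."""

    def __init__(self, message: str, *, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ContractError(CrosspathError):
    """An operation's precondition was violated by the caller."""


class ConfigurationError(CrosspathError):
    """A configuration value is invalid; the message names the field."""

    def __init__(self, field: str, message: str):
        super().__init__(f"{field}: {message}")
        self.field = field
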