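"""Exception hierarchy shared across the pipeline stages."""


class NetpharmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NetpharmError):
    """A tabular input is structurally malformed (e.g. a required column is missing)."""


class RowError(NetpharmError):
    """A single data row failed to parse; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class IntegrityError(NetpharmError):
    """Input violates a structural invariant (duplicate keys, non-simple graph...)."""


class LookupError_(NetpharmError):
    """A referenced identifier is unknown to the object being queried."""


class ConfigError(NetpharmError):
    """Invalid configuration; may carry several messages at once."""

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))
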