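"""Exception types shared across the package."""


class RecordFormatError(ValueError):
    """A delimited input row does not match the declared layout."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


class ConfigurationError(ValueError):
    """Mismatched dimensions, modes or options."""


class CapabilityError(RuntimeError):
    """A requested component (e.g. an external encoder) is unavailable."""


class InputError(ValueError):
    """Invalid data passed to a training or evaluation routine."""
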