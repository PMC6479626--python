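class ConfigError(ValueError):
    """A scenario/environment configuration value is invalid.

    Carries the offending field name so CLI error messages can point at it.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")
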