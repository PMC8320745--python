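"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """A run configuration is internally inconsistent or violates a precondition."""
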