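"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument or configuration value is outside its admissible range."""


class DataError(ValueError):
    """An input table, interval file or matrix violates its contract."""
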