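"""Exception types used across the package.

``ConfigError`` covers invalid parameters, schemes, and run configuration;
``DataError`` covers malformed or inconsistent input data. The CLI maps them
to exit codes 2 and 3 respectively.
"""


class ConfigError(ValueError):
    """Invalid configuration (parameters, scheme, thresholds)."""


class DataError(ValueError):
    """Malformed or internally inconsistent input data."""
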