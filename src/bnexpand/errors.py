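"""Package-wide exception types."""


class BnexpandError(Exception):
    """Base class for all bnexpand errors."""


class DataError(BnexpandError, ValueError):
    """Malformed or inconsistent input data (bad file, bad counts, bad ids)."""


class ConfigError(BnexpandError, ValueError):
    """Invalid configuration value (threshold out of range, bad fraction...)."""
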