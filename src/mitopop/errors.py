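"""Exception types shared across the package."""


class MitopopError(Exception):
    """Base class for package errors."""


class AlignmentError(MitopopError):
    """Malformed alignment input (unequal lengths, bad characters, ...)."""


class MetadataError(MitopopError):
    """Sample metadata missing, duplicated, or inconsistent with the alignment."""


class ConfigError(MitopopError):
    """Invalid run or simulation configuration."""
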