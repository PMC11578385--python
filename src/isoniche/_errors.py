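"""Exception hierarchy shared across isoniche."""


class IsonicheError(Exception):
    """Base class for all isoniche errors."""


class FormatError(IsonicheError, ValueError):
    """A file does not conform to the expected on-disk format."""


class IntegrityError(IsonicheError, ValueError):
    """Parsed data violates a structural invariant (duplicates, negatives...)."""


class ConfigError(IsonicheError, ValueError):
    """A configuration value is missing, inconsistent, or out of range."""
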