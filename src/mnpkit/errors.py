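"""Exception hierarchy shared across the toolkit.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class MNPKitError(Exception):
    """Base class for all mnpkit errors."""


class ConfigError(MNPKitError):
    """Invalid configuration value or combination."""


class DataError(MNPKitError):
    """Invalid, inconsistent or missing input data."""


class GenerationError(DataError):
    """The simulator could not honour the requested layout (e.g. planted
    loci cannot be placed without overlap)."""
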