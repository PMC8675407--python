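"""Exception hierarchy shared across the package."""


class MegasiteError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MegasiteError):
    """A user-supplied specification or option is invalid."""


class DataError(MegasiteError):
    """Input data violate a structural requirement."""


class FormatError(MegasiteError):
    """A file is not in the expected on-disk format."""


class EstimationError(MegasiteError):
    """A statistical quantity is undefined for the given data."""
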