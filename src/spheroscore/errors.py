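"""Exception hierarchy shared across the package."""


class SpheroscoreError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SpheroscoreError, ValueError):
    """A value, parameter, or input record violates a documented contract."""


class ConfigurationError(SpheroscoreError, ValueError):
    """A run-level configuration problem (unknown backend, missing calibration...)."""


class ImageIOError(SpheroscoreError, OSError):
    """An image or table could not be read or written."""
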