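"""Exception hierarchy shared across the package."""


class NirsBundleError(Exception):
    """Base class for all package errors."""


class ConfigError(NirsBundleError):
    """Invalid configuration (bad parameter values, malformed config files)."""


class DataError(NirsBundleError):
    """Invalid or inconsistent input data (intensities, timestamps, schemas)."""


class GeometryError(NirsBundleError):
    """Invalid probe geometry (bad separations, unknown optodes, duplicates)."""
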