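"""Exception hierarchy shared across the package."""


class ActimetryError(Exception):
    """Base class for all package-specific errors."""


class MonitorFormatError(ActimetryError):
    """A monitor file violates the 42-column TSV contract."""


class MetadataError(ActimetryError):
    """Condition metadata is inconsistent (duplicate channels, missing file...)."""


class ImputationError(ActimetryError):
    """Missing values cannot be imputed (e.g. no channel observed at a timestamp)."""


class ParameterError(ActimetryError):
    """An analysis parameter is out of its valid range."""


class RangeError(ActimetryError):
    """A requested window lies outside the data span."""
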