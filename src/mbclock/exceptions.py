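"""Exception hierarchy shared across the package."""


class MbclockError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MbclockError, ValueError):
    """An invalid simulation, model, or pipeline configuration."""


class SchemaError(MbclockError, ValueError):
    """A metadata or feature table is missing required structure."""


class FormatError(MbclockError, ValueError):
    """A file on disk does not parse as the declared format."""


class ConsistencyError(MbclockError, ValueError):
    """Two objects that must agree (ids, shapes) do not."""
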