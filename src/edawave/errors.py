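"""Exception types shared across the package."""


class EdaWaveError(Exception):
    """Base class for all edawave errors."""


class InvalidInputError(EdaWaveError, ValueError):
    """An argument violates a documented precondition."""


class CorruptBlockError(EdaWaveError, ValueError):
    """A compressed block cannot be decoded consistently."""


class UndefinedMetricError(EdaWaveError, ValueError):
    """A metric is undefined for the given inputs (e.g. zero denominator)."""


class ConfigurationError(EdaWaveError, ValueError):
    """A configuration cannot be realised (e.g. an unmeetable filter spec)."""
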