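"""Package-wide exception types."""


class CattlesegError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CattlesegError):
    """A model or run configuration is inconsistent."""


class DimensionError(CattlesegError):
    """An input array has an illegal spatial size; names the offending axis."""


class DataError(CattlesegError):
    """A dataset, mask or annotation is malformed."""


class UndefinedMetricError(CattlesegError):
    """A metric is requested on data for which it is undefined."""


class TrainingError(CattlesegError):
    """Training aborted; the message carries lr/iteration/batch diagnostics."""
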