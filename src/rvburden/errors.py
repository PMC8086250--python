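"""Exception hierarchy shared across the pipeline stages."""


class RvBurdenError(Exception):
    """Base class for all package errors."""


class ConfigError(RvBurdenError):
    """Invalid configuration (bad frequencies, missing fields, bad paths). CLI exit code 2."""


class DataError(RvBurdenError):
    """Inconsistent or unusable input data (e.g. alt reads without depth). CLI exit code 3."""


class ClassificationError(DataError):
    """A variant cannot be classified (unknown consequence term, missing boundary annotation)."""


class QCError(DataError):
    """A sample cannot be QC'd (missing coverage metric)."""
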