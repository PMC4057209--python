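"""Exception types shared across the pipeline stages."""


class CerebTFAError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(CerebTFAError, ValueError):
    """A configuration object violates its invariants."""


class ValidationError(CerebTFAError, ValueError):
    """An input value is outside its physiological or mathematical domain."""


class InsufficientDataError(CerebTFAError, ValueError):
    """A series is too short for the requested window or segmentation."""


class UnsupportedOperationError(CerebTFAError, ValueError):
    """The requested operation is deliberately refused (e.g. upsampling)."""


class IngestError(CerebTFAError, ValueError):
    """A raw file or recording failed structural checks at ingest."""


class BandResolutionError(CerebTFAError, ValueError):
    """A frequency band contains no spectral bins at the current resolution."""


class DegenerateSampleError(CerebTFAError, ValueError):
    """A paired sample carries no usable information (all differences zero)."""
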