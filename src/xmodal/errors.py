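"""Exception hierarchy. CLI maps ConfigError to exit 2 and DataError to exit 3."""


class XmodalError(Exception):
    """Base class for package errors."""


class ConfigError(XmodalError):
    """Invalid configuration, parameter out of range, or unknown config key."""


class DataError(XmodalError):
    """Invalid or insufficient input data."""


class AnnotationError(DataError):
    """A bounding-box annotation does not fit its image."""


class EmptyBagError(DataError):
    """A histology bag with no patches reached an encoder."""


class TooFewPairsError(DataError):
    """Fewer than two same-patient cross-modal pairs are available."""


class DegenerateTaskError(DataError):
    """Training labels contain a single class."""


class ContractError(XmodalError):
    """An internal interface contract was violated (modality/shape mismatch)."""


class DivergenceError(XmodalError):
    """Training produced a non-finite loss."""
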