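"""Exception hierarchy shared across the pipeline stages."""


class HistodeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(HistodeError, ValueError):
    """A synthetic-data specification violates its invariants."""


class InvalidConfigError(HistodeError, ValueError):
    """A stage configuration violates its invariants."""


class InvalidDatasetError(HistodeError, ValueError):
    """An input dataset cannot support the requested operation."""


class DecodeError(HistodeError, ValueError):
    """An image file could not be decoded."""


class ParseError(HistodeError, ValueError):
    """A feature-matrix file could not be parsed."""


class LabelSetError(HistodeError, ValueError):
    """A label outside the declared class set was encountered."""


class PairingError(HistodeError, ValueError):
    """Two report sets could not be paired by classifier family."""
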