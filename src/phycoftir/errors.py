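"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`PhycoFTIRError`, so callers can catch one type at pipeline level.
"""


class PhycoFTIRError(Exception):
    """Base class for all phycoftir errors."""


class FormatError(PhycoFTIRError):
    """A file could not be parsed as the declared format."""


class SpectrumValidationError(PhycoFTIRError):
    """A spectrum violates its structural invariants."""


class RangeError(PhycoFTIRError):
    """A wavenumber window or grid falls outside the data span."""


class DegenerateInputError(PhycoFTIRError):
    """Input is degenerate for the requested operation (e.g. constant trace)."""


class ContractError(PhycoFTIRError):
    """An operation was called outside its documented contract."""


class ConfigError(PhycoFTIRError):
    """A pipeline configuration is invalid."""
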