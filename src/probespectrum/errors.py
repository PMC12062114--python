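"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`ProbeSpectrumError`, so callers (and the CLI) can distinguish
validation failures from genuine bugs.
"""


class ProbeSpectrumError(Exception):
    """Base class for all probespectrum errors."""


class InputError(ProbeSpectrumError):
    """Malformed or empty input file."""


class AlignmentShapeError(InputError):
    """Sequences in an alignment do not share one gapped length."""


class MetadataError(InputError):
    """Panel metadata table is inconsistent with the alignment."""


class CoordinateError(ProbeSpectrumError):
    """A position cannot be mapped between coordinate systems."""


class DesignError(ProbeSpectrumError):
    """A probe cannot be designed at the requested site."""


class ConfigurationError(ProbeSpectrumError):
    """The requested operation is impossible for this panel/configuration."""


class ValidationError(ProbeSpectrumError):
    """A data table violates its invariants."""
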