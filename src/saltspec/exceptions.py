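"""Exception hierarchy shared by all pipeline stages."""


class SaltspecError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SaltspecError):
    """Invalid simulation or analysis configuration (negative variance, bad counts...)."""


class FormatError(SaltspecError):
    """A file or table does not match the expected schema."""


class BandMissingError(SaltspecError):
    """A requested wavelength is outside the spectral grid (beyond tolerance)."""


class BalanceError(SaltspecError):
    """The trial layout is not a balanced RCBD (missing genotype x replicate cells)."""


class AlignmentError(SaltspecError):
    """Two objects that must share labels/order do not."""
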