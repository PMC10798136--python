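"""Exception types shared across the package."""


class MscoutError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MscoutError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class InputError(MscoutError, ValueError):
    """An operation received input outside its contract."""


class InsufficientAlignmentError(MscoutError, ValueError):
    """Too few comparable codon columns to estimate substitution rates."""


class UnalignableError(MscoutError, ValueError):
    """A cDNA could not be colinearly placed on the genomic sequence."""
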