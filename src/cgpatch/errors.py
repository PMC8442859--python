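"""Exception types shared across the package."""


class CgpatchError(Exception):
    """Base class for package errors."""


class ConfigurationError(CgpatchError):
    """A parameter or configuration value is invalid or inconsistent."""


class DataError(CgpatchError):
    """Input data violate a structural requirement (shape, encoding, labels)."""


class VcfFormatError(DataError):
    """A VCF record cannot be used (malformed or multiallelic)."""
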