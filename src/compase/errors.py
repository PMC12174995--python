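"""Exception hierarchy shared across the package."""


class CompaseError(Exception):
    """Base class for all package-specific errors."""


class InputError(CompaseError):
    """A required input is missing, empty, or unusable."""


class FormatError(CompaseError):
    """An input file violates its format contract."""


class TagError(CompaseError):
    """Alignment records lack the configured AS/NM tags too often."""
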