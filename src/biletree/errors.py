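"""Exception hierarchy shared across the package."""


class BiletreeError(Exception):
    """Base class for all package-specific errors (validation failures)."""


class MGFParseError(BiletreeError):
    """A spectrum block in an MGF file could not be parsed."""


class TreeConfigError(BiletreeError):
    """A filtering-tree configuration is structurally invalid."""


class FormulaError(BiletreeError):
    """A molecular formula string is empty, malformed, or uses an unknown element."""
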