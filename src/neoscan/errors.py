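"""Exception hierarchy."""


class NeoscanError(Exception):
    """Base class for all neoscan errors."""


class ValidationError(NeoscanError):
    """Malformed input: bad alphabet, bad coordinates, ragged alignment."""


class BracketNotFoundError(NeoscanError):
    """ACA-bracket template extraction failed (no second bracket)."""


class LayoutError(NeoscanError):
    """Fixed sequence elements cannot be placed as requested."""


class NormalizationError(NeoscanError):
    """Strand-count normalization is impossible (e.g. zero spike reads)."""
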