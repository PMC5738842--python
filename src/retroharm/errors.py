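"""Exception hierarchy shared across the package."""


class RetroharmError(Exception):
    """Base class for all package errors."""


class FormatError(RetroharmError):
    """A file does not conform to its declared layout (columns, types)."""


class IntegrityError(RetroharmError):
    """Data violates a structural invariant (duplicates, broken totals)."""


class SpecError(RetroharmError):
    """A harmonisation spec is malformed or inconsistent with a dictionary."""


class TransformError(RetroharmError):
    """A recode/binning operation met a value it cannot handle."""
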