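"""Exception hierarchy shared across the package."""


class HogmriError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HogmriError):
    """A file could not be read or has an unsupported layout."""


class ValidationError(HogmriError, ValueError):
    """Input data violates a stated invariant (e.g. non-finite voxels)."""


class DegenerateInputError(HogmriError, ValueError):
    """Input is structurally valid but degenerate for the operation
    (constant image, volume smaller than one cell, ...)."""


class SchemaError(HogmriError, ValueError):
    """Tabular inputs do not line up (mismatched ids, feature spaces)."""
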