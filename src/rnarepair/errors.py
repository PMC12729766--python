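"""Exception hierarchy shared across the package."""


class RnaRepairError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RnaRepairError, ValueError):
    """An argument or configuration violates a documented invariant."""


class FormatError(RnaRepairError, ValueError):
    """An on-disk file is malformed or inconsistent with its companions."""


class EmptyResultError(RnaRepairError, ValueError):
    """A filtering step removed everything; the caller must relax thresholds."""


class LookupError_(RnaRepairError, KeyError):
    """A requested gene/protein id is absent from the matrix."""


class ShapeError(RnaRepairError, ValueError):
    """Matrix dimensions do not line up."""
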