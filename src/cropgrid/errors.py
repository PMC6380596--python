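"""Exception hierarchy for cropgrid."""


class CropGridError(Exception):
    """Base class for all cropgrid errors."""


class SizingError(CropGridError):
    """Grid too small to host the requested administrative structure."""


class SchemaError(CropGridError):
    """A file or table is missing a required field or has a malformed one."""


class ValidationError(CropGridError):
    """Input data violate a structural invariant."""


class AllocationInfeasibleError(CropGridError):
    """An SRU demands area that cannot be placed on its pixels."""

    def __init__(self, message: str, sru_id=None, crop_id=None):
        super().__init__(message)
        self.sru_id = sru_id
        self.crop_id = crop_id


class DegeneratePriorError(CropGridError):
    """All-zero prior for a crop/system that carries positive area."""


class ConvergenceError(CropGridError):
    """The entropy solver failed to reach the requested tolerance."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class UnsupportedDirectionError(CropGridError):
    """Statistics can only be degraded to a coarser admin level."""


class UndefinedStatisticError(CropGridError):
    """A statistic is undefined on the given input (empty or zero-variance)."""


class ExcludedPixelError(CropGridError):
    """Pixel similarity is undefined when both values are zero."""
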