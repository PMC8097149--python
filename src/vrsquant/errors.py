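"""Package-specific exceptions."""


class VrsquantError(Exception):
    """Base class for vrsquant errors."""


class ConfigurationError(VrsquantError):
    """A configuration value violates an invariant (e.g. an infeasible
    correlation matrix, a non-positive spacing, a negative group size)."""


class PlacementError(VrsquantError):
    """Overlap-free tubule placement could not be completed: the requested
    burden does not fit in the supraventricular white matter at the
    configured grid size."""


class MaskingError(VrsquantError):
    """A masking operation received degenerate input (empty volume, empty
    ventricle mask, fewer intensity levels than tissue classes)."""
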