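"""Exception hierarchy for leafgas."""


class LeafgasError(Exception):
    """Base class for all leafgas errors."""


class SchemaError(LeafgasError):
    """Input table does not match the expected schema (missing/duplicate columns,
    empty data block, duplicate timestamps)."""


class GeometryError(LeafgasError):
    """Invalid chamber/leaf geometry."""


class PhaseError(LeafgasError):
    """Light-phase segmentation failed or produced an unexpected layout."""


class SteadyStateError(LeafgasError):
    """A steady-state window could not be evaluated."""


class ConfigurationError(LeafgasError):
    """A required configuration value (e.g. g_smax estimator coefficients)
    was not supplied."""
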