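"""Exception hierarchy for the wristemg pipeline."""


class WristEmgError(Exception):
    """Base class for all package-specific errors."""


class DataError(WristEmgError):
    """Input data violates a contract (non-finite values, empty arrays, ...)."""


class FilterDesignError(WristEmgError):
    """Invalid digital-filter request (e.g. cutoff at or above Nyquist)."""


class SyncError(WristEmgError):
    """Synchronization trace unusable (no rising edge found)."""


class SchemaError(WristEmgError):
    """File content does not match the documented session layout."""


class GeometryError(WristEmgError):
    """Degenerate marker configuration (coincident or collinear points)."""


class ParameterError(WristEmgError):
    """Invalid parameter combination."""


class TrialRejectionError(DataError):
    """Trial invalidated by excessive marker gaps or out-of-range frames."""


class PipelineError(WristEmgError):
    """A pipeline stage failed; message names the stage."""
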