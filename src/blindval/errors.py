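"""Exception hierarchy.

Every rejection in the package raises a distinct subclass of
:class:`BlindvalError` so callers (and the CLI) can map failures to
specific exit messages.
"""


class BlindvalError(Exception):
    """Base class for all package errors."""


class ShapeMismatchError(BlindvalError):
    """Two masks with different raster dimensions were compared."""


class ImageIdMismatchError(BlindvalError):
    """Two masks of different images were compared."""


class MaskIOError(BlindvalError):
    """A mask file could not be read, or is degenerate (zero size)."""


class CatalogError(BlindvalError):
    """The annotation catalog is not a complete image x source grid."""


class ScheduleError(BlindvalError):
    """Infeasible duplicate spec or inconsistent plan/provenance."""


class ProvenanceError(BlindvalError):
    """Sealed provenance file is corrupt, truncated, or not a bijection."""


class BlindingError(BlindvalError):
    """Provenance was offered to (or found inside) the blinded review stage."""


class ResponseError(BlindvalError):
    """Duplicate presentation id, unknown label, or malformed response."""


class IncompleteLogError(BlindvalError):
    """An analysis required responses that are missing from the log."""

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class AnalysisError(BlindvalError):
    """Invalid statistic input (e.g. n = 0 proportion, n < 2 t-interval)."""
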