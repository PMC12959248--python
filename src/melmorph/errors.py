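"""Exception hierarchy.

Errors are split so that callers can distinguish "this slide had no tumour"
(a countable analysis outcome) from I/O, schema and numerical failures.
"""


class MelmorphError(Exception):
    """Base class for all package errors."""


class CalibrationError(MelmorphError):
    """Missing or implausible micron-per-pixel calibration."""


class MaskFormatError(MelmorphError):
    """Image cannot be interpreted as a single-channel binary mask."""


class SchemaError(MelmorphError):
    """A table is missing a mandatory column or has an unparseable value."""


class NoTumourError(MelmorphError):
    """Mask contains no foreground pixels (no segmented invasive melanoma)."""


class DegenerateGeometryError(MelmorphError):
    """Geometry collapsed to zero width (e.g. collinear contour points)."""


class FitError(MelmorphError):
    """A statistical fit failed (non-convergence, separation, no usable pairs)."""


class GeneratorError(MelmorphError):
    """Synthetic-data specification invalid or calibration unattainable."""


class PipelineError(MelmorphError):
    """Fatal end-to-end pipeline failure (zero cases, ID mismatch)."""
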