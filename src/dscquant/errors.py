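"""Exception hierarchy for the DSC-MRI quantification pipeline.

Every stage raises a subclass of :class:`DscQuantError` so that the CLI can
attach the stage name and a remediation hint before propagating.
"""


class DscQuantError(Exception):
    """Base class for all pipeline errors."""


class DimensionalityError(DscQuantError):
    """Input volume does not have the expected number of dimensions."""


class MetadataError(DscQuantError):
    """Required acquisition metadata (TE, frame spacing) is missing."""


class GridError(DscQuantError):
    """Two volumes do not share a voxel grid (shape and/or affine)."""


class MaskError(DscQuantError):
    """A required mask is empty or malformed."""


class InsufficientFramesError(DscQuantError):
    """Too few dynamic frames remain for the requested operation."""


class ScaleError(DscQuantError):
    """Wavelet scales incompatible with the curve length."""


class NoBolusError(DscQuantError):
    """No contrast bolus could be located on the signal-time curve."""


class BoundaryError(DscQuantError):
    """Detected bolus trough sits on the first or last frame."""


class BaselineError(DscQuantError):
    """Pre-bolus baseline window is too short."""


class ConversionError(DscQuantError):
    """Signal-to-concentration conversion failed (non-positive baseline)."""


class FitError(DscQuantError):
    """Leakage-model regression is degenerate."""


class ParameterError(DscQuantError):
    """A user-supplied parameter is out of its valid range."""


class EmptyRoiError(DscQuantError):
    """A region of interest came out empty after exclusions."""


class LabelError(DscQuantError):
    """Requested label value is absent from a label volume."""


class DegenerateHistogramError(DscQuantError):
    """Intensity histogram has fewer than two distinct values."""


class NormalizationError(DscQuantError):
    """White-matter reference mean is non-positive."""


class StatsError(DscQuantError):
    """ROI statistics undefined (no finite voxels)."""


class PairingError(DscQuantError):
    """Paired measurement vectors have different lengths."""


class CompletenessError(DscQuantError):
    """Ratings table has missing cells."""


class DegenerateDataError(DscQuantError):
    """Statistic undefined because the data carry no variance."""


class SpecError(DscQuantError):
    """Phantom specification is internally inconsistent."""
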