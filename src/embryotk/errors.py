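"""Exception hierarchy for embryotk.

Every error raised deliberately by the toolkit derives from :class:`EmbryotkError`
so batch drivers can distinguish pipeline failures from programming errors.
"""


class EmbryotkError(Exception):
    """Base class for all embryotk errors."""


class DimensionMismatchError(EmbryotkError):
    """Slices or channels do not share dimensions; message names the offender."""


class NoInputError(EmbryotkError):
    """An input directory contained no usable image files."""


class CorruptFileError(EmbryotkError):
    """A file failed to parse (bad magic, truncated payload, ...)."""


class UnsupportedEncodingError(EmbryotkError):
    """NRRD encoding not among raw / gzip / bzip2."""


class UnsupportedDtypeError(EmbryotkError):
    """Sample type outside the supported uint8 / uint16 / float32 set."""


class DegenerateInputError(EmbryotkError):
    """Operation undefined on this input (e.g. Otsu of a constant image)."""


class DegenerateOutputError(EmbryotkError):
    """Operation would produce an empty result (e.g. bin factor > extent)."""


class EmptyForegroundError(EmbryotkError):
    """Autocrop found no voxel above threshold; manual crop is required."""


class BoundsError(EmbryotkError):
    """A box or rectangle falls outside the volume it is applied to."""


class ChannelMismatchError(EmbryotkError):
    """Multi-channel crop propagation received channels of differing shape."""


class InterpolationModeError(EmbryotkError):
    """Linear interpolation requested for an integer label map."""


class AlignmentError(EmbryotkError):
    """Volumes expected to share a grid (dims + spacing) do not."""


class LabelNotFoundError(EmbryotkError):
    """An edit referenced a label id absent from the label map."""


class UnresolvedAnnotationError(EmbryotkError):
    """An annotation referenced a candidate level or region that does not exist."""


class NamingViolationError(EmbryotkError):
    """A specimen filename does not follow the DATE_ALLELE_ZYGOSITY_SEX convention."""


class PhantomSpecError(EmbryotkError):
    """A phantom specification is internally inconsistent."""
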