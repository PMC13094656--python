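"""Named exception types raised across the package.

Every degenerate input the pipelines can meet maps to a distinct class so
callers (and the CLI) can report which stage failed and why.
"""


class MucospotError(Exception):
    """Base class for all package-specific errors."""


class ChannelIndexError(MucospotError):
    """A channel map points at a page/plane that the TIFF does not contain."""


class ChannelShapeMismatchError(MucospotError):
    """Channels assembled into one image do not share height x width."""


class GeometryMismatchError(MucospotError):
    """Two rasters that must be pixel-aligned have different shapes."""


class ConstantImageError(MucospotError):
    """Thresholding was asked for on a constant (zero-contrast) grid."""


class EmptyTableError(MucospotError):
    """An operation needing at least one object received none."""


class ZeroVarianceError(MucospotError):
    """Correlation/regression input has no variance in one variable."""


class InfeasiblePackingError(MucospotError):
    """The scene spec asks for more nuclei than fit at the minimum separation."""


class StageError(MucospotError):
    """Wraps an error raised inside a pipeline stage with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
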