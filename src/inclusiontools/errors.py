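"""Exception and warning types shared across the package."""


class InclusionToolsError(Exception):
    """Base class for all package errors."""


class GeometryError(InclusionToolsError):
    """A geometric precondition is violated (disk outside image, empty scaled ROI...)."""


class ThresholdError(InclusionToolsError):
    """Automatic thresholding is impossible (e.g. constant image)."""


class EmptyROIError(InclusionToolsError):
    """An operation requiring a non-empty pixel set received an empty one."""


class ChannelRoleError(InclusionToolsError):
    """A required channel role cannot be resolved in the input image."""


class SchemaError(InclusionToolsError):
    """A tabular input violates its published column schema."""


class CalibrationError(InclusionToolsError):
    """Gate calibration sets are degenerate (too small or identical populations)."""


class SeparabilityWarning(UserWarning):
    """Emitted when a fitted gate barely separates its calibration populations."""
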