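"""Exception hierarchy shared across the pipeline stages."""


class NephroradiomicsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NephroradiomicsError):
    """A configuration object is internally inconsistent or incomplete."""


class RangeError(NephroradiomicsError, ValueError):
    """A scalar input falls outside its documented domain."""


class CapacityError(NephroradiomicsError):
    """A requested phantom geometry cannot be realized on the voxel grid."""


class EmptyVOIError(NephroradiomicsError):
    """A mask contains no voxels where a nonempty VOI is required."""


class DegenerateInputError(NephroradiomicsError):
    """Statistical input is degenerate (constant series, single class, ...)."""


class GeometryMismatchError(NephroradiomicsError):
    """Volumes belonging to one subject disagree in shape or spacing."""


class FeatureComputationError(NephroradiomicsError):
    """A feature evaluated to NaN/Inf or an unknown feature was requested."""
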