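"""Exception hierarchy for somasearch.

Every error raised deliberately by the package derives from
:class:`SomasearchError`, so callers can catch pipeline failures without
catching programming errors.
"""


class SomasearchError(Exception):
    """Base class for all somasearch errors."""


class InvalidParameterError(SomasearchError, ValueError):
    """A parameter is outside its legal range."""


class GridMismatchError(SomasearchError, ValueError):
    """A volume's shape does not match the grid it is bound to."""


class InvalidCenterError(SomasearchError, ValueError):
    """A searchlight center lies outside the brain mask."""


class DatasetError(SomasearchError, ValueError):
    """A decoding dataset is incomplete or degenerate."""


class DegenerateSphereError(SomasearchError, ValueError):
    """A sphere has no usable voxels for the requested statistic."""


class DegenerateCovariateError(SomasearchError, ValueError):
    """A behavioural covariate has zero variance."""


class AlignmentError(SomasearchError, ValueError):
    """Subject identifiers of two inputs do not match."""


class ConfigError(SomasearchError, ValueError):
    """A pipeline configuration file is malformed."""
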