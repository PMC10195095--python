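"""Named exception types shared across the package."""


class MyoconductError(Exception):
    """Base class for all package errors."""


class MissingSpacingError(MyoconductError):
    """Voxel spacing was not provided and could not be found in metadata."""


class AnisotropicSpacingError(MyoconductError):
    """Voxel spacing differs between axes; only isotropic grids are supported."""


class DatasetNotFoundError(MyoconductError):
    """A named HDF5 dataset does not exist in the file."""


class NonVolumeDataError(MyoconductError):
    """The stored data are not a 3D volume."""


class SubstackExtentError(MyoconductError):
    """Requested substack extent exceeds the physical size of the volume."""


class TissueSpecError(MyoconductError):
    """A synthetic tissue specification is inconsistent or unsatisfiable."""


class AnalyticModelError(MyoconductError):
    """A spec lies outside the assumptions of the closed-form conductivity."""


class CalibrationError(MyoconductError):
    """Gap-junction conductivity calibration failed (no coupled pairs)."""


class OverlapError(MyoconductError):
    """Class masks that must be disjoint overlap."""


class DegenerateFitError(MyoconductError):
    """Regression input has no variance in the predictor."""


class SolverConvergenceError(MyoconductError):
    """The linear solver did not reach the requested residual norm."""
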