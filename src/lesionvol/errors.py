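"""Exception hierarchy shared across the pipeline."""


class LesionVolError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(LesionVolError):
    """A specification or configuration references undefined quantities."""


class PlacementError(LesionVolError):
    """A synthetic lesion could not be placed under its geometric constraints."""


class EmptySceneError(LesionVolError):
    """No foreground voxels were found where a brain was expected."""


class InputError(LesionVolError):
    """Invalid numeric input (empty mask, nonpositive voxel dimensions, ...)."""


class GeometryError(LesionVolError):
    """Degenerate landmarks or mismatched grids."""


class SeedError(LesionVolError):
    """A ventricle seed voxel does not lie in CSF."""


class PipelineError(LesionVolError):
    """An upstream product required for calibration is missing or empty."""


class CollinearityError(LesionVolError):
    """Regression design matrix is rank deficient."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = list(columns)


class UndefinedEffectError(LesionVolError):
    """Effect size undefined (pooled standard deviation is zero)."""
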