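"""Exception hierarchy for the lesionmap package.

Exit-code mapping used by the CLI: ConfigError -> 2, data errors -> 3,
computation errors -> 4.
"""


class LesionMapError(Exception):
    """Base class for all package errors."""


class ConfigError(LesionMapError):
    """Invalid or unresolvable pipeline configuration."""


class FormatError(LesionMapError):
    """A file exists but cannot be parsed in the expected format."""


class DimensionalityError(FormatError):
    """A volume has the wrong number of dimensions for its role."""


class GridMismatchError(LesionMapError):
    """Two volumes do not share a compatible grid (shape + affine)."""


class EmptyMaskError(LesionMapError):
    """A binary mask that must be nonempty has no set voxels."""


class DegenerateSeedError(LesionMapError):
    """A seed time course has zero variance; correlation is undefined."""


class MissingLabelError(FormatError):
    """Nonzero atlas labels are absent from the label table."""

    def __init__(self, missing_ids):
        self.missing_ids = sorted(int(i) for i in missing_ids)
        super().__init__(
            f"atlas labels missing from label table: {self.missing_ids}"
        )


class InsufficientSubjectsError(LesionMapError):
    """Fewer subjects than the statistical operation requires."""


class UndefinedDiceError(LesionMapError):
    """Dice index of two empty masks is undefined."""


class GeometryError(LesionMapError):
    """A requested synthetic shape does not fit inside its container."""


class KindError(LesionMapError):
    """A StatMap of the wrong statistic kind was supplied."""


class PipelineStageError(LesionMapError):
    """Wraps a failure with the pipeline stage and offending input id."""

    def __init__(self, stage: str, input_id: str, cause: Exception):
        self.stage = stage
        self.input_id = input_id
        self.cause = cause
        super().__init__(f"stage '{stage}' failed on '{input_id}': {cause}")
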