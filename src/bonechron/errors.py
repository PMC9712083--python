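"""Exception hierarchy shared across bonechron modules."""


class BonechronError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BonechronError):
    """A required column is missing or a table cannot be interpreted."""


class RowError(BonechronError):
    """A single row failed validation; carries the zero-based row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class InsufficientDataError(BonechronError):
    """Too few records for the requested fit or estimate."""


class DegenerateDesignError(BonechronError):
    """The regression design is singular (e.g. zero variance in MAT)."""


class UndefinedRateError(BonechronError):
    """A sighting rate is undefined (reference age equals youngest age)."""


class PipelineError(BonechronError):
    """A pipeline stage failed; annotated with region and stage."""

    def __init__(self, region: str, stage: str, cause: Exception):
        self.region = region
        self.stage = stage
        self.cause = cause
        super().__init__(f"region {region!r}, stage {stage!r}: {cause}")
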