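"""Exception hierarchy shared across the pipeline stages."""


class Adipo3dError(Exception):
    """Base class for all package errors."""


class ParameterError(Adipo3dError, ValueError):
    """A parameter value is outside its valid domain."""


class GeometryError(Adipo3dError, ValueError):
    """A synthetic geometry could not be constructed (domain too small,
    spheres could not be placed without contact, ...)."""

    def __init__(self, message: str, placed: int | None = None):
        super().__init__(message)
        self.placed = placed


class InputError(Adipo3dError, ValueError):
    """An input stack or table violates the stage's contract."""


class SchemaError(InputError):
    """A table is missing required columns."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"table is missing required columns: {self.missing}")


class ModelError(Adipo3dError, ValueError):
    """A statistical model cannot be fit (rank deficiency, single-level
    factor, ...)."""
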