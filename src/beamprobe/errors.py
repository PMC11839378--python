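"""Exception hierarchy shared across the package."""


class BeamprobeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BeamprobeError, ValueError):
    """An object or argument violates a documented invariant."""


class SchemaError(BeamprobeError, KeyError):
    """A container file is missing a required field.

    The offending field name is stored in ``field``.
    """

    def __init__(self, field: str, path: str = ""):
        self.field = field
        self.path = path
        where = f" in {path!r}" if path else ""
        super().__init__(f"missing required field {field!r}{where}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return self.args[0]


class ContractViolationError(BeamprobeError):
    """A network-under-test broke its callable contract."""


class ZeroVarianceError(ValidationError):
    """Correlation is undefined because one input has zero variance."""


class TruncationWarning(UserWarning):
    """A simulated echo falls partly outside the recording window."""
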