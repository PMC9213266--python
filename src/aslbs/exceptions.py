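"""Exception hierarchy shared across the package.

CLI exit-code mapping: :class:`ParameterError` -> 2, every other
:class:`AslBsError` -> 3.
"""


class AslBsError(Exception):
    """Base class for all package errors."""


class ParameterError(AslBsError, ValueError):
    """A user-supplied parameter is out of its admissible range."""


class StructuralError(AslBsError, ValueError):
    """Inputs are structurally inconsistent (shape/ordering/schema)."""


class DegenerateDataError(AslBsError, ValueError):
    """Input data are valid in form but degenerate for the operation."""


class ResourceError(AslBsError, RuntimeError):
    """The requested computation exceeds a configured resource cap."""
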