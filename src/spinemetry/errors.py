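"""Exception hierarchy for the spinemetry pipeline.

Every failure mode raises a distinct subclass of :class:`SpinemetryError`
so that callers (and the CLI) can report the failing stage precisely.
The pipeline's policy is to fail loudly: degenerate geometry, missing
annotations and incomplete study designs are errors, never silently
defaulted values, because a zero or imputed metric would poison the
downstream deformation ratios.
"""

from __future__ import annotations


class SpinemetryError(Exception):
    """Base class for all spinemetry errors."""


class AnnotationParseError(SpinemetryError):
    """Raised for syntactically malformed annotation documents."""

    def __init__(self, message: str, *, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)


class AnnotationValidationError(SpinemetryError):
    """Raised when a document violates the annotation schema.

    ``path`` names the offending location, e.g. ``polygons[0].vertices``.
    """

    def __init__(self, message: str, *, path: str = ""):
        self.path = path
        if path:
            message = f"{path}: {message}"
        super().__init__(message)


class CohortConflictError(SpinemetryError):
    """Two documents claim the same (volunteer, modality, phase, load) cell."""


class DegenerateGeometryError(SpinemetryError):
    """Zero-area polygon, coincident landmark points, or collapsed extents."""


class IncompleteAnnotationError(SpinemetryError):
    """A document lacks a required polygon/landmark for the requested region."""


class InsufficientLandmarksError(SpinemetryError):
    """Scaling-factor derivation is missing a horizontal or vertical pair."""


class PairingError(SpinemetryError):
    """Two records that must share identifying keys do not."""


class ReferenceConditionError(SpinemetryError):
    """The normalization reference is not the pre-procedure 1.8 kg condition."""


class IncompleteDesignError(SpinemetryError):
    """The cohort is missing cells of the loads x phases design.

    ``missing`` enumerates (volunteer, region, phase, load_kg) tuples.
    """

    def __init__(self, message: str, *, missing: list[tuple] | None = None):
        self.missing = missing or []
        if self.missing:
            shown = ", ".join(map(str, self.missing[:10]))
            more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
            message = f"{message}: {shown}{more}"
        super().__init__(message)


class InfeasibleTargetError(SpinemetryError):
    """Requested polygon targets violate area <= width * height."""


class EmptyGroupError(SpinemetryError):
    """Summary statistics requested for an empty group."""


class PipelineStageError(SpinemetryError):
    """Wraps a module error with the name of the failing workflow stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
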