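"""Exception hierarchy.

Per-level measurement failures (missing labels, empty cross-sections,
everything excluded by the caudal rule) are data findings and carry the
anatomical level so callers can report and continue; format and schema
problems are hard errors.
"""


class CanalGradeError(Exception):
    """Base class for all package errors."""


class FormatError(CanalGradeError):
    """Unreadable or unsupported on-disk representation."""


class DimensionalityError(FormatError):
    """Image is not a 3D volume."""


class VocabularyError(CanalGradeError):
    """A label value has no entry in the label vocabulary."""


class GeometryMismatchError(CanalGradeError):
    """Label volume grid/geometry does not match its paired image."""


class SchemaError(CanalGradeError):
    """Tabular file is missing required columns."""


class ValidationError(CanalGradeError):
    """Invalid parameter or out-of-range value."""


class LevelError(CanalGradeError):
    """Base for per-level measurement failures; carries the level id."""

    def __init__(self, level: str, message: str):
        self.level = level
        super().__init__(f"{level}: {message}")


class LevelSkippedError(LevelError):
    """IVD label missing or too small to fit a plane."""


class LevelUnmeasurableError(LevelError):
    """No valid plane remains after exclusion rules."""


class ReferenceUnavailableError(LevelError):
    """No mid-vertebral reference frame can be built for the level."""


class RatioUnavailableError(LevelError):
    """Reference measurement invalid or non-positive; ratios undefined."""


class UndefinedMeasurementError(CanalGradeError):
    """Measurement requested on an empty canal cross-section."""


class OutOfBoundsError(CanalGradeError):
    """Requested plane frame lies outside the volume bounding box."""


class DegenerateMetricError(CanalGradeError):
    """Statistic undefined for the given inputs (e.g. single-class labels)."""
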