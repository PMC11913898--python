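"""In-memory containers for image and label volumes.

Physical coordinates follow the ITK/DICOM LPS convention: +x left,
+y posterior, +z superior (cranial).  A voxel index ``(i, j, k)`` maps to
the physical point ``origin + direction @ (spacing * index)``.  Arrays are
stored in index order ``(i, j, k)`` so this mapping applies directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import ndimage

from .errors import GeometryMismatchError, ValidationError, VocabularyError

# Patient-space reference directions (LPS).
CRANIAL_AXIS = np.array([0.0, 0.0, 1.0])
AP_AXIS = np.array([0.0, 1.0, 0.0])  # anterior -> posterior

#: Lumbar IVD levels, caudal to cranial.
LUMBAR_LEVELS = ("L5-S1", "L4-L5", "L3-L4", "L2-L3", "L1-L2", "T12-L1")

#: Vertebrae spanning those levels, caudal to cranial.
LUMBAR_VERTEBRAE = ("S1", "L5", "L4", "L3", "L2", "L1", "T12")

CANAL_ROLE = "canal"


def cranial_vertebra(level: str) -> str:
    """Vertebra cranially adjacent to an IVD level, e.g. ``L4-L5 -> L4``."""
    return level.split("-")[0]


def default_vocabulary() -> dict[int, str]:
    """Default integer-label convention.

    Canal = 100; vertebrae numbered 1..7 caudal-to-cranial (S1..T12); each
    IVD gets 200 plus the label of its cranial vertebra.  This is a package
    convention — segmentation tools differ, so a custom mapping can always
    be supplied as JSON.
    """
    vocab: dict[int, str] = {100: CANAL_ROLE}
    for i, vert in enumerate(LUMBAR_VERTEBRAE, start=1):
        vocab[i] = f"vertebra:{vert}"
    for level in LUMBAR_LEVELS:
        vert_label = LUMBAR_VERTEBRAE.index(cranial_vertebra(level)) + 1
        vocab[200 + vert_label] = f"ivd:{level}"
    return vocab


def _check_geometry(spacing, origin, direction):
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float).reshape(3, 3)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValidationError(f"spacing must be 3 positive reals, got {spacing}")
    if abs(abs(np.linalg.det(direction)) - 1.0) > 1e-6:
        raise ValidationError("direction matrix must have |det| = 1")
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-6):
        raise ValidationError("direction matrix columns must be orthonormal")
    return spacing, origin, direction


@dataclass
class ImageVolume:
    """3D scalar intensity grid with physical geometry metadata."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(f"expected a 3D grid, got {self.voxels.ndim}D")
        self.spacing, self.origin, self.direction = _check_geometry(
            self.spacing, self.origin, self.direction
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices (..., 3) to physical mm points."""
        index = np.asarray(index, dtype=float)
        return self.origin + (index * self.spacing) @ self.direction.T

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map physical mm points (..., 3) to continuous voxel indices."""
        points = np.asarray(points, dtype=float)
        return ((points - self.origin) @ self.direction) / self.spacing

    def same_geometry(self, other: "ImageVolume | LabelVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-5)
            and np.allclose(self.origin, other.origin, atol=1e-3)
            and np.allclose(self.direction, other.direction, atol=1e-6)
        )


@dataclass
class LabelVolume(ImageVolume):
    """Integer segmentation grid sharing geometry with a paired image.

    ``vocabulary`` maps integer labels to roles: ``"canal"``,
    ``"vertebra:<name>"`` or ``"ivd:<level>"``.
    """

    vocabulary: dict[int, str] = field(default_factory=default_vocabulary)

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValidationError("label grid must be integer-valued")
        present = set(np.unique(self.voxels).tolist()) - {0}
        unknown = sorted(present - set(self.vocabulary))
        if unknown:
            raise VocabularyError(
                f"labels {unknown} are not in the vocabulary"
            )

    @property
    def labels(self) -> np.ndarray:
        return self.voxels

    def _label_for_role(self, role: str) -> int | None:
        for value, r in self.vocabulary.items():
            if r == role:
                return value
        return None

    def role_mask(self, role: str) -> np.ndarray:
        value = self._label_for_role(role)
        if value is None:
            raise VocabularyError(f"role {role!r} not in vocabulary")
        return self.labels == value

    @cached_property
    def canal_mask(self) -> np.ndarray:
        """Canal mask reduced to its largest 26-connected component.

        Guards measurements against segmentation speckle; a stray island
        would otherwise distort the caudal extent and the plane ranking.
        """
        mask = self.role_mask(CANAL_ROLE)
        if not mask.any():
            return mask
        comp, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        if n <= 1:
            return mask
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        return comp == (int(np.argmax(sizes)) + 1)

    def ivd_mask(self, level: str) -> np.ndarray:
        return self.role_mask(f"ivd:{level}")

    def vertebra_mask(self, name: str) -> np.ndarray:
        return self.role_mask(f"vertebra:{name}")

    def ivd_levels(self) -> list[str]:
        """IVD levels present in the vocabulary *and* the grid, caudal first."""
        present = set(np.unique(self.labels).tolist())
        levels = [
            role.split(":", 1)[1]
            for value, role in self.vocabulary.items()
            if role.startswith("ivd:") and value in present
        ]
        order = {lvl: i for i, lvl in enumerate(LUMBAR_LEVELS)}
        return sorted(levels, key=lambda l: order.get(l, 99))

    def paired_with(self, image: ImageVolume) -> "LabelVolume":
        """Validate co-registration with ``image``; returns self."""
        if not self.same_geometry(image):
            raise GeometryMismatchError(
                "label volume geometry does not match the paired image"
            )
        return self


def binarize_grades(grades) -> np.ndarray:
    """Collapse ordinal severity grades to stenosis flags.

    Grades 0 and 1 (none/mild) map to 0 = no stenosis; grades 2 and 3
    (moderate/severe) map to 1 = stenosis.
    """
    grades = np.asarray(grades)
    if grades.size and (grades.min() < 0 or grades.max() > 3):
        raise ValidationError("grades must be integers in {0, 1, 2, 3}")
    return (grades >= 2).astype(int)
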