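"""Plane fitting and canal-orthogonal oblique reslicing.

Each IVD gets a 3D plane fitted by principal component analysis of its
voxel coordinates; the eigenvector with the smallest eigenvalue (the
disc's thin axis) is the plane normal and defines the angulation of the
reconstructed "angled axial" view.  Mid-vertebral reference frames average
the angulation of the two neighbouring discs.  The volume is then
resampled into a stack of thin slices orthogonal to that normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    LevelSkippedError,
    OutOfBoundsError,
    ReferenceUnavailableError,
    ValidationError,
)
from .volume import AP_AXIS, CRANIAL_AXIS, ImageVolume, LabelVolume

log = logging.getLogger(__name__)

#: Reconstructed slice thickness / in-plane pixel size, mm.
SLICE_STEP_MM = 0.5
#: Half-extent of the per-level slice stack along the normal, mm.
#: With 0.5 mm steps this yields 41 slice centres (mid-slice ± 20) spanning
#: a 2 cm range, enough to cover a healthy disc plus its endplates.
HALF_EXTENT_MM = 10.0
#: In-plane margin added around the canal bounding box, mm.
INPLANE_MARGIN_MM = 10.0

MIN_IVD_VOXELS = 10


@dataclass(frozen=True)
class PlaneFrame:
    """Oriented measurement plane.

    ``normal`` points cranially; ``axes`` are two in-plane unit vectors,
    the second being the patient antero-posterior direction projected
    into the plane, so the AP diameter can be read off slice columns.
    """

    level: str
    center: np.ndarray
    normal: np.ndarray
    axes: tuple[np.ndarray, np.ndarray]

    def __post_init__(self):
        u, v = self.axes
        basis = np.stack([u, v, self.normal])
        if not np.allclose(basis @ basis.T, np.eye(3), atol=1e-6):
            raise ValidationError("plane frame axes must be orthonormal")
        if float(self.normal @ CRANIAL_AXIS) < -1e-9:
            raise ValidationError("plane normal must point cranially")


@dataclass
class PlaneStack:
    """Canal-orthogonal resampled slices for one level.

    ``intensity[s]`` and ``canal[s]`` are the slice at ``offsets[s]`` mm
    along the frame normal; array axis 0 follows ``frame.axes[0]`` and
    axis 1 the in-plane AP axis.  ``grid_origin`` gives the in-plane mm
    coordinates of pixel (0, 0) relative to the frame centre.
    """

    frame: PlaneFrame
    offsets: np.ndarray
    intensity: np.ndarray  # (n_slices, na, nb)
    canal: np.ndarray      # (n_slices, na, nb) bool
    pixel_spacing: float
    grid_origin: tuple[float, float]

    @property
    def n_slices(self) -> int:
        return len(self.offsets)

    def slice_center(self, s: int) -> np.ndarray:
        """Physical centre of slice ``s`` (frame centre shifted along normal)."""
        return self.frame.center + self.offsets[s] * self.frame.normal


def build_frame(level: str, center: np.ndarray, normal: np.ndarray) -> PlaneFrame:
    """Orthonormal frame from a centre and (unnormalised) normal."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    if float(normal @ CRANIAL_AXIS) < 0:
        normal = -normal
    ap = AP_AXIS - (AP_AXIS @ normal) * normal
    if np.linalg.norm(ap) < 1e-6:
        # Degenerate: plane orthogonal to AP; fall back to the left-right axis.
        ap = np.array([1.0, 0.0, 0.0])
        ap = ap - (ap @ normal) * normal
    ap = ap / np.linalg.norm(ap)
    u = np.cross(ap, normal)
    return PlaneFrame(level=level, center=np.asarray(center, dtype=float),
                      normal=normal, axes=(u, ap))


def fit_ivd_plane(labels: LabelVolume, level: str) -> PlaneFrame:
    """Fit the IVD plane of ``level`` by PCA of its voxel coordinates.

    The covariance eigenvector with the smallest eigenvalue is the disc's
    through-plane axis; it is sign-flipped to point cranially.
    """
    mask = labels.ivd_mask(level)
    n = int(mask.sum())
    if n < MIN_IVD_VOXELS:
        raise LevelSkippedError(level, f"IVD label has {n} voxels "
                                f"(need >= {MIN_IVD_VOXELS})")
    pts = labels.index_to_physical(np.argwhere(mask))
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    normal = eigvecs[:, int(np.argmin(eigvals))]
    return build_frame(level, center, normal)


def reference_frame(labels: LabelVolume, vertebra: str,
                    cranial_ivd: PlaneFrame | None,
                    caudal_ivd: PlaneFrame | None) -> PlaneFrame:
    """Mid-vertebral reference frame at the centroid of ``vertebra``.

    The reference angulation is the (renormalised) mean of the two
    neighbouring IVD normals — the spherical bisector for two unit
    vectors — or the single available normal if only one disc exists.
    """
    neighbors = [f.normal for f in (cranial_ivd, caudal_ivd) if f is not None]
    if not neighbors:
        raise ReferenceUnavailableError(
            vertebra, "no neighbouring IVD frame for reference angulation")
    mask = labels.vertebra_mask(vertebra)
    if not mask.any():
        raise ReferenceUnavailableError(vertebra, "vertebra label is empty")
    center = labels.index_to_physical(np.argwhere(mask)).mean(axis=0)
    normal = np.mean(neighbors, axis=0)
    if np.linalg.norm(normal) < 1e-9:
        raise ReferenceUnavailableError(
            vertebra, "neighbouring normals cancel; angulation undefined")
    return build_frame(f"ref:{vertebra}", center, normal)


def resample_plane_stack(image: ImageVolume, labels: LabelVolume,
                         frame: PlaneFrame,
                         half_extent_mm: float = HALF_EXTENT_MM,
                         step_mm: float = SLICE_STEP_MM) -> PlaneStack:
    """Reslice image + canal mask orthogonally to ``frame.normal``.

    Intensities are sampled with trilinear interpolation, the canal mask
    with nearest-neighbour.  The in-plane field of view covers the canal's
    projected bounding box plus a fixed margin; samples falling outside
    the volume are zero-padded (with a logged warning).
    """
    u, v = frame.axes
    idx = image.physical_to_index(frame.center)
    if np.any(idx < -0.5) or np.any(idx > np.array(image.shape) - 0.5):
        raise OutOfBoundsError(f"frame centre {frame.center} outside volume")

    canal_pts = labels.index_to_physical(np.argwhere(labels.canal_mask))
    if len(canal_pts):
        rel = canal_pts - frame.center
        a_lo, a_hi = rel @ u, rel @ u
        a_lo, a_hi = float(np.min(a_lo)), float(np.max(a_hi))
        b = rel @ v
        b_lo, b_hi = float(np.min(b)), float(np.max(b))
    else:
        a_lo = a_hi = b_lo = b_hi = 0.0
    a_vals = np.arange(a_lo - INPLANE_MARGIN_MM, a_hi + INPLANE_MARGIN_MM + step_mm / 2,
                       step_mm)
    b_vals = np.arange(b_lo - INPLANE_MARGIN_MM, b_hi + INPLANE_MARGIN_MM + step_mm / 2,
                       step_mm)
    offsets = np.arange(-half_extent_mm, half_extent_mm + step_mm / 2, step_mm)
    if half_extent_mm == 0:
        offsets = np.array([0.0])

    pts = (frame.center
           + offsets[:, None, None, None] * frame.normal
           + a_vals[None, :, None, None] * u
           + b_vals[None, None, :, None] * v)
    coords = image.physical_to_index(pts)          # (ns, na, nb, 3)
    cc = np.moveaxis(coords, -1, 0)                # (3, ns, na, nb)

    shape = np.array(image.shape)
    outside = np.any((cc < -0.5) | (cc > (shape - 0.5)[:, None, None, None]), axis=0)
    if outside.any():
        log.warning("%s: %d of %d samples fall outside the volume; zero-padded",
                    frame.level, int(outside.sum()), outside.size)

    intensity = ndimage.map_coordinates(image.voxels.astype(float), cc,
                                        order=1, mode="constant", cval=0.0)
    canal = ndimage.map_coordinates(labels.canal_mask.astype(np.uint8), cc,
                                    order=0, mode="constant", cval=0)
    return PlaneStack(frame=frame, offsets=offsets, intensity=intensity,
                      canal=canal.astype(bool), pixel_spacing=step_mm,
                      grid_origin=(float(a_vals[0]), float(b_vals[0])))
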