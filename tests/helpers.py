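"""Shared builders for synthetic geometric test objects."""

from __future__ import annotations

import numpy as np

from canalgrade.volume import ImageVolume, LabelVolume

CANAL_ONLY_VOCAB = {100: "canal"}


def make_cylinder_study(radius_mm: float = 6.0, tilt_deg: float = 0.0,
                        spacing: float = 0.5, extent=(50.0, 50.0, 60.0),
                        intensity_inside: float = 300.0,
                        intensity_outside: float = 80.0):
    """Straight cylindrical 'canal' tilted about the left-right axis.

    The cylinder axis passes through the volume centre, tilted by
    ``tilt_deg`` from the cranio-caudal axis in the y-z plane.  Returns
    (image, labels, center, axis_unit_vector).
    """
    t = np.deg2rad(tilt_deg)
    axis = np.array([0.0, np.sin(t), np.cos(t)])
    extent = np.asarray(extent, dtype=float)
    shape = np.ceil(extent / spacing).astype(int)
    origin = -extent / 2.0
    coords = [origin[d] + spacing * np.arange(shape[d]) for d in range(3)]
    X = coords[0][:, None, None]
    Y = coords[1][None, :, None]
    Z = coords[2][None, None, :]
    # squared distance from the axis through the origin
    dot = Y * axis[1] + Z * axis[2]
    d2 = X**2 + Y**2 + Z**2 - dot**2
    mask = d2 <= radius_mm**2
    labels = np.where(mask, 100, 0).astype(np.int16)
    img = np.where(mask, intensity_inside, intensity_outside)
    geometry = dict(spacing=(spacing,) * 3, origin=origin, direction=np.eye(3))
    image = ImageVolume(img, **geometry)
    label_vol = LabelVolume(labels, vocabulary=CANAL_ONLY_VOCAB, **geometry)
    return image, label_vol, np.zeros(3), axis


def make_disc_mask(normal: np.ndarray, semi_axes=(15.0, 10.0, 2.0),
                   spacing: float = 0.5, extent=(40.0, 40.0, 40.0),
                   label: int = 204, center=None):
    """Voxelised flat ellipsoid ('disc') with its thin axis along ``normal``.

    Returns a LabelVolume whose only nonzero label is ``label`` (an IVD
    role under the default vocabulary when 204 = L3-L4).
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    # complete an orthonormal basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    extent = np.asarray(extent, dtype=float)
    shape = np.ceil(extent / spacing).astype(int)
    origin = -extent / 2.0
    coords = [origin[d] + spacing * np.arange(shape[d]) for d in range(3)]
    pts = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1)
    if center is not None:
        pts = pts - np.asarray(center, dtype=float)
    a = pts @ e1
    b = pts @ e2
    d = pts @ normal
    sa = semi_axes
    mask = (a / sa[0])**2 + (b / sa[1])**2 + (d / sa[2])**2 <= 1.0
    labels = np.where(mask, label, 0).astype(np.int16)
    return LabelVolume(labels, spacing=(spacing,) * 3,
                       origin=origin if center is None else origin + center,
                       direction=np.eye(3))


def random_unit_tilt(rng, max_tilt_deg: float = 30.0) -> np.ndarray:
    """Random unit vector within ``max_tilt_deg`` of the cranial axis."""
    tilt = np.deg2rad(rng.uniform(0.0, max_tilt_deg))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.sin(tilt) * np.cos(phi),
                     np.sin(tilt) * np.sin(phi),
                     np.cos(tilt)])
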