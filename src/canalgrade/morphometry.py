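"""Per-plane stenosis metrics and per-level feature extraction.

Three metrics are computed on every reconstructed canal-orthogonal plane:

* CSA — dural sac cross-sectional area, the summed pixel area of the
  canal mask (mm²);
* APD — the largest antero-posterior extent of the canal mask (mm),
  spanning disconnected components if the mask splits;
* FSL — fluid (CSF) signal, the mean T2 intensity inside the canal mask;
  low values indicate CSF effacement.

Planes inside the most caudal 15 mm of the canal are discarded (the dural
sac tapers naturally there and would mimic stenosis).  Remaining planes
are ranked per metric, ascending — for all three, smaller means more
stenotic — and the plane with the lowest cumulative rank is taken as the
most stenotic.  Its metrics, divided by a mid-vertebral reference
measurement at the cranially adjacent vertebra, give the ratio features
rCSA / rAPD / rFSL that normalise out patient and level size differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    LevelError,
    LevelSkippedError,
    LevelUnmeasurableError,
    OutOfBoundsError,
    RatioUnavailableError,
    ReferenceUnavailableError,
    UndefinedMeasurementError,
    VocabularyError,
)
from .geometry import (
    HALF_EXTENT_MM,
    SLICE_STEP_MM,
    PlaneFrame,
    PlaneStack,
    fit_ivd_plane,
    reference_frame,
    resample_plane_stack,
)
from .volume import (
    CRANIAL_AXIS,
    LUMBAR_LEVELS,
    LUMBAR_VERTEBRAE,
    ImageVolume,
    LabelVolume,
    cranial_vertebra,
)

log = logging.getLogger(__name__)

#: Most caudal extent of the canal excluded from measurement, mm.
CAUDAL_EXCLUSION_MM = 15.0


@dataclass
class PlaneMeasurement:
    offset_mm: float
    csa: float = 0.0
    apd: float = 0.0
    fsl: float = 0.0
    valid: bool = True


@dataclass
class LevelFeatureVector:
    """Six metrics of the most stenotic plane at one IVD level."""

    study_id: str
    level: str
    csa: float
    apd: float
    fsl: float
    r_csa: float | None = None
    r_apd: float | None = None
    r_fsl: float | None = None
    grade: int | None = None
    qc: dict = field(default_factory=dict, repr=False)

    @property
    def complete(self) -> bool:
        return self.r_csa is not None

    def as_record(self) -> dict:
        return {
            "study_id": self.study_id, "level": self.level,
            "csa": self.csa, "apd": self.apd, "fsl": self.fsl,
            "r_csa": self.r_csa, "r_apd": self.r_apd, "r_fsl": self.r_fsl,
            "grade": self.grade,
        }


def measure_csa(canal_slice: np.ndarray, pixel_spacing: float) -> float:
    """Mask area: true-pixel count times pixel area (mm²)."""
    return float(np.count_nonzero(canal_slice)) * pixel_spacing**2


def measure_apd(canal_slice: np.ndarray, pixel_spacing: float,
                ap_axis=(0.0, 1.0)) -> float:
    """Largest AP extent of the mask along the in-plane AP direction.

    Pixel centres are projected onto ``ap_axis`` (a unit 2-vector in slice
    coordinates; the default is the stack's AP-aligned column axis); the
    extent is max − min plus one pixel spacing for the pixel width, which
    is unbiased for axis-aligned shapes.  Disconnected components count
    toward the same extent: the measure is the largest possible distance.
    """
    ij = np.argwhere(canal_slice)
    if len(ij) == 0:
        raise UndefinedMeasurementError("empty canal mask; APD undefined")
    ax = np.asarray(ap_axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    proj = (ij * pixel_spacing) @ ax
    return float(proj.max() - proj.min()) + pixel_spacing


def measure_fsl(intensity_slice: np.ndarray, canal_slice: np.ndarray) -> float:
    """Mean intensity over canal-mask pixels."""
    mask = np.asarray(canal_slice, dtype=bool)
    if not mask.any():
        raise UndefinedMeasurementError("empty canal mask; FSL undefined")
    return float(np.asarray(intensity_slice, dtype=float)[mask].mean())


def canal_caudal_end(labels: LabelVolume) -> float:
    """Cranio-caudal (superior) coordinate of the most caudal canal voxel."""
    pts = labels.index_to_physical(np.argwhere(labels.canal_mask))
    if len(pts) == 0:
        raise UndefinedMeasurementError("canal mask is empty")
    return float((pts @ CRANIAL_AXIS).min())


def measure_planes(stack: PlaneStack, labels: LabelVolume) -> list[PlaneMeasurement]:
    """Measure every plane of a stack and apply the validity rules.

    A plane is invalid when its centre lies strictly within 15 mm of the
    canal's caudal end along the patient cranio-caudal axis (15.0 mm
    exactly remains valid) or when the canal cross-section is empty —
    an empty mask would otherwise always win the stenosis ranking.
    """
    caudal_end = canal_caudal_end(labels)
    out: list[PlaneMeasurement] = []
    for s in range(stack.n_slices):
        m = PlaneMeasurement(offset_mm=float(stack.offsets[s]))
        mask = stack.canal[s]
        height = float(stack.slice_center(s) @ CRANIAL_AXIS) - caudal_end
        if height < CAUDAL_EXCLUSION_MM or not mask.any():
            m.valid = False
            out.append(m)
            continue
        m.csa = measure_csa(mask, stack.pixel_spacing)
        m.apd = measure_apd(mask, stack.pixel_spacing)
        m.fsl = measure_fsl(stack.intensity[s], mask)
        out.append(m)
    return out


def apply_caudal_exclusion(stack: PlaneStack, labels: LabelVolume) -> list[PlaneMeasurement]:
    """Alias of :func:`measure_planes`; raises if no plane survives."""
    meas = measure_planes(stack, labels)
    if not any(m.valid for m in meas):
        raise LevelUnmeasurableError(stack.frame.level,
                                     "all planes excluded or empty")
    return meas


def select_most_stenotic(measurements: list[PlaneMeasurement]) -> int:
    """Index of the most stenotic valid plane by cumulative rank.

    Valid planes are ranked ascending per metric (smallest CSA, APD, FSL
    each get rank 1; ties take the mean rank) and the plane with the
    lowest rank sum wins.  Rank-sum ties break toward smaller CSA, then
    the more caudal offset.
    """
    valid_idx = [i for i, m in enumerate(measurements) if m.valid]
    if not valid_idx:
        raise LevelUnmeasurableError("?", "no valid plane to rank")
    csa = np.array([measurements[i].csa for i in valid_idx])
    apd = np.array([measurements[i].apd for i in valid_idx])
    fsl = np.array([measurements[i].fsl for i in valid_idx])
    rank_sum = rankdata(csa) + rankdata(apd) + rankdata(fsl)
    offs = np.array([measurements[i].offset_mm for i in valid_idx])
    # lexicographic: rank sum, then CSA, then caudal-most (smallest offset)
    order = np.lexsort((offs, csa, rank_sum))
    return valid_idx[int(order[0])]


def compute_ratios(level_meas: PlaneMeasurement,
                   ref_meas: PlaneMeasurement) -> tuple[float, float, float]:
    """Level-to-reference ratios (rCSA, rAPD, rFSL)."""
    if not ref_meas.valid or min(ref_meas.csa, ref_meas.apd, ref_meas.fsl) <= 0:
        raise RatioUnavailableError("?", "reference measurement invalid or zero")
    return (level_meas.csa / ref_meas.csa,
            level_meas.apd / ref_meas.apd,
            level_meas.fsl / ref_meas.fsl)


def _neighbour_levels(vertebra: str) -> tuple[str | None, str | None]:
    """IVD levels cranial and caudal to a vertebra (None past the ends)."""
    i = LUMBAR_VERTEBRAE.index(vertebra)
    caudal = LUMBAR_LEVELS[i - 1] if i >= 1 else None
    cranial = LUMBAR_LEVELS[i] if i < len(LUMBAR_LEVELS) else None
    return cranial, caudal


def measure_reference(image: ImageVolume, labels: LabelVolume, level: str,
                      level_frame: PlaneFrame) -> PlaneMeasurement:
    """Single mid-vertebral reference measurement for ``level``.

    Taken at the centroid of the cranially adjacent vertebra, on one plane
    whose angulation averages the two neighbouring IVD normals.  The same
    validity rules apply as for level planes.
    """
    vert = cranial_vertebra(level)
    try:
        cranial_level, caudal_level = _neighbour_levels(vert)
    except ValueError:
        raise ReferenceUnavailableError(level, f"unknown vertebra {vert}")
    frames: dict[str, PlaneFrame | None] = {"cranial": None, "caudal": None}
    for key, lvl in (("cranial", cranial_level), ("caudal", caudal_level)):
        if lvl == level:
            frames[key] = level_frame
        elif lvl is not None:
            try:
                frames[key] = fit_ivd_plane(labels, lvl)
            except LevelSkippedError:
                pass
    try:
        ref = reference_frame(labels, vert, frames["cranial"], frames["caudal"])
    except VocabularyError:
        raise ReferenceUnavailableError(level, f"vertebra {vert} not in vocabulary")
    stack = resample_plane_stack(image, labels, ref, half_extent_mm=0.0)
    meas = measure_planes(stack, labels)
    return meas[0]


def measure_level(image: ImageVolume, labels: LabelVolume, level: str,
                  study_id: str = "study") -> LevelFeatureVector:
    """Full per-level measurement: six metrics of the most stenotic plane.

    Fits the IVD plane, reslices a 41-plane stack, applies the validity
    rules, selects the most stenotic plane by cumulative rank, and divides
    by the mid-vertebral reference.  Levels without a usable reference
    (e.g. T12-L1 with no T12 in the mask) keep their absolute metrics but
    have the ratios set to None and are excluded from classifier training.
    """
    frame = fit_ivd_plane(labels, level)
    stack = resample_plane_stack(image, labels, frame)
    meas = apply_caudal_exclusion(stack, labels)
    best = select_most_stenotic(meas)
    sel = meas[best]
    fv = LevelFeatureVector(study_id=study_id, level=level,
                            csa=sel.csa, apd=sel.apd, fsl=sel.fsl)
    fv.qc = {
        "selected_offset_mm": sel.offset_mm,
        "n_valid_planes": int(sum(m.valid for m in meas)),
        "normal": frame.normal.tolist(),
    }
    try:
        ref = measure_reference(image, labels, level, frame)
        fv.r_csa, fv.r_apd, fv.r_fsl = compute_ratios(sel, ref)
        fv.qc["reference"] = {"csa": ref.csa, "apd": ref.apd, "fsl": ref.fsl}
    except (ReferenceUnavailableError, RatioUnavailableError,
            UndefinedMeasurementError, LevelUnmeasurableError,
            OutOfBoundsError) as exc:
        log.info("%s %s: reference unavailable (%s); ratios omitted",
                 study_id, level, exc)
    return fv


def measure_study(image: ImageVolume, labels: LabelVolume,
                  study_id: str = "study",
                  levels: list[str] | None = None
                  ) -> tuple[list[LevelFeatureVector], dict[str, str]]:
    """Measure every IVD level present; returns (records, per-level errors)."""
    labels.paired_with(image)
    records: list[LevelFeatureVector] = []
    errors: dict[str, str] = {}
    for level in levels or labels.ivd_levels():
        try:
            records.append(measure_level(image, labels, level, study_id))
        except LevelError as exc:
            errors[level] = str(exc)
            log.warning("%s %s: skipped (%s)", study_id, level, exc)
    return records, errors


def records_to_frame(records: list[LevelFeatureVector]) -> pd.DataFrame:
    return pd.DataFrame([r.as_record() for r in records])
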