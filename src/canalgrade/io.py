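"""On-disk formats: volumes, label maps, feature tables, grades, models, reports.

Volumes and label maps go through SimpleITK (NIfTI, MetaImage, NRRD).
Feature and grade tables are CSV; vocabularies, configs and evaluation
reports are JSON.  Reading never rescales or recasts intensities.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .errors import DimensionalityError, FormatError, SchemaError, ValidationError
from .volume import ImageVolume, LabelVolume, binarize_grades, default_vocabulary

FEATURE_COLUMNS = [
    "study_id", "level", "csa", "apd", "fsl", "r_csa", "r_apd", "r_fsl", "grade",
]
#: Decimal places kept in feature CSVs; finer than the 0.5 mm sampling grid.
FEATURE_PRECISION = 4


def _sitk_to_arrays(img: sitk.Image):
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"expected a 3D volume, got {img.GetDimension()}D"
        )
    # GetArrayFromImage returns (k, j, i); store index-order (i, j, k).
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.array(img.GetSpacing())
    origin = np.array(img.GetOrigin())
    direction = np.array(img.GetDirection()).reshape(3, 3)
    return arr, spacing, origin, direction


def read_volume(path) -> ImageVolume:
    """Read a 3D intensity volume (.nii/.nii.gz/.mha/.nrrd)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps all reader failures
        raise FormatError(f"cannot read {path}: {exc}") from exc
    arr, spacing, origin, direction = _sitk_to_arrays(img)
    return ImageVolume(arr, spacing, origin, direction)


def write_volume(vol: ImageVolume, path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    img.SetDirection(tuple(vol.direction.ravel()))
    sitk.WriteImage(img, str(path))


def read_labels(path, vocabulary: dict[int, str] | None = None,
                paired_with: ImageVolume | None = None) -> LabelVolume:
    """Read an integer label volume and map labels to anatomical roles.

    Non-integer voxel values are rejected rather than rounded; a label
    value without a vocabulary entry raises naming the offending label.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    arr, spacing, origin, direction = _sitk_to_arrays(img)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.mod(arr, 1) == 0):
            raise ValidationError(f"{path} contains non-integer label values")
        arr = arr.astype(np.int64)
    lab = LabelVolume(arr, spacing, origin, direction,
                      vocabulary=vocabulary or default_vocabulary())
    if paired_with is not None:
        lab.paired_with(paired_with)
    return lab


def write_labels(lab: LabelVolume, path) -> None:
    write_volume(ImageVolume(lab.labels.astype(np.int32), lab.spacing,
                             lab.origin, lab.direction), path)


def read_vocabulary(path) -> dict[int, str]:
    """Load a JSON label vocabulary ({"100": "canal", ...})."""
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def write_vocabulary(vocab: dict[int, str], path) -> None:
    with open(path, "w") as fh:
        json.dump({str(k): v for k, v in vocab.items()}, fh, indent=2)


# ---------------------------------------------------------------------------
# feature and grade tables

def write_feature_table(records: pd.DataFrame, path) -> None:
    """Write per-level features as CSV with a fixed column order."""
    df = pd.DataFrame(records, columns=FEATURE_COLUMNS)
    df.to_csv(path, index=False, float_format=f"%.{FEATURE_PRECISION}f")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    return df[FEATURE_COLUMNS]


def read_grade_table(path) -> pd.DataFrame:
    """Read per-level severity grades: study_id, level, grade (+ binary)."""
    df = pd.read_csv(path)
    missing = [c for c in ("study_id", "level", "grade") if c not in df.columns]
    if missing:
        raise SchemaError(f"grade table missing columns: {missing}")
    df = df.copy()
    df["binary"] = binarize_grades(df["grade"].to_numpy())
    return df


def write_grade_table(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(df, columns=["study_id", "level", "grade"])
    out["binary"] = binarize_grades(out["grade"].to_numpy())
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# models and reports

def save_model(bundle: dict, path) -> None:
    """Persist a fitted model bundle (model + manifest) to one file."""
    if "model" not in bundle or "manifest" not in bundle:
        raise ValidationError("model bundle needs 'model' and 'manifest'")
    joblib.dump(bundle, path)


def load_model(path) -> dict:
    bundle = joblib.load(path)
    if not isinstance(bundle, dict) or "model" not in bundle:
        raise FormatError(f"{path} is not a canalgrade model bundle")
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
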