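"""Reading and writing CT volumes, label maps and feature tables.

Supported external formats: DICOM series and NIfTI-1 for volumes,
NIfTI-1 plus a JSON class legend for label maps, RFC-4180 CSV for
feature tables.  HU calibration (DICOM rescale slope/intercept) is
applied on read.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .model import (
    ANNOTATION_CLASSES,
    ANNOTATION_COLUMN,
    FEATURE_COLUMNS,
    ID_COLUMNS,
    CTVolume,
    LabelMap,
    SegClass,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "write_feature_csv",
    "read_feature_csv",
    "validate_feature_table",
]


def _affine(spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"`` or ``"dicom-series"``; when omitted it
    is inferred (directories are treated as DICOM series).  DICOM stored
    values are rescaled to HU via RescaleSlope/RescaleIntercept.  A DICOM
    series with gaps in its instance numbering raises an error naming the
    missing indices; anisotropic spacing only warns.
    """
    path = Path(path)
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom-series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown volume format: {format!r}")


def _read_nifti(path: Path) -> CTVolume:
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    _warn_if_anisotropic(spacing)
    return CTVolume(data, spacing, origin)


def _read_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in Path(path).iterdir()
                   if p.is_file() and p.suffix.lower() in {".dcm", ".ima", ""})
    if not files:
        raise FileNotFoundError(f"no DICOM files under {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda d: int(d.InstanceNumber))
    numbers = [int(d.InstanceNumber) for d in slices]
    expected = set(range(numbers[0], numbers[-1] + 1))
    missing = sorted(expected - set(numbers))
    if missing:
        raise ValueError(f"DICOM series is missing slice indices: {missing}")

    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1:
        z0 = float(slices[0].ImagePositionPatient[2])
        z1 = float(slices[1].ImagePositionPatient[2])
        dz = abs(z1 - z0) or float(getattr(first, "SliceThickness", dx))
    else:
        dz = float(getattr(first, "SliceThickness", dx))
    spacing = (dx, dy, dz)
    _warn_if_anisotropic(spacing)

    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    # pixel_array is (rows, cols) = (y, x); volume axes are (x, y, z)
    data = np.stack(planes, axis=-1).transpose(1, 0, 2)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return CTVolume(data, spacing, origin)


def _warn_if_anisotropic(spacing) -> None:
    if len({round(s, 9) for s in spacing}) != 1:
        warnings.warn(f"anisotropic voxel spacing {spacing}", stacklevel=3)


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (float32)."""
    path = Path(path)
    img = nib.Nifti1Image(volume.voxels.astype(np.float32),
                          _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))
    return path


def write_labelmap(labels: LabelMap, path: str | Path) -> Path:
    """Write a label map as integer NIfTI-1 with a JSON class legend.

    The legend (``<path stem>.legend.json``) maps integer codes to class
    names so the file is self-describing.
    """
    path = Path(path)
    known = {int(c) for c in SegClass}
    present = {int(v) for v in np.unique(labels.labels)}
    unknown = sorted(present - known)
    if unknown:
        raise ValueError(f"unknown class codes in label map: {unknown}")
    img = nib.Nifti1Image(labels.labels.astype(np.uint8), _affine(labels.spacing))
    nib.save(img, str(path))
    legend = {int(c): c.name for c in SegClass}
    legend_path = _legend_path(path)
    legend_path.write_text(json.dumps(legend, indent=1))
    return path


def _legend_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return path.with_name(name + ".legend.json")


def read_labelmap(path: str | Path) -> LabelMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.uint8)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(data, spacing)


def validate_feature_table(table: pd.DataFrame) -> None:
    """Check the feature-table schema and its internal invariants."""
    missing = [c for c in ID_COLUMNS + FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    if ANNOTATION_COLUMN in table.columns:
        bad = set(table[ANNOTATION_COLUMN].dropna()) - set(ANNOTATION_CLASSES)
        if bad:
            raise ValueError(f"unknown annotation classes: {sorted(bad)}")


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> Path:
    """Export a feature table to CSV at full float precision."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    validate_feature_table(table)
    cols = list(ID_COLUMNS + FEATURE_COLUMNS)
    if ANNOTATION_COLUMN in table.columns:
        cols.append(ANNOTATION_COLUMN)
    path = Path(path)
    table[cols].to_csv(path, index=False, float_format="%.17g", lineterminator="\n")
    return path


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_feature_table(table)
    return table
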