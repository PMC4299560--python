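"""Volume, mask and table input/output.

CT volumes travel either as DICOM series (one file per slice, written by
:mod:`ctild.dicomio`) or as NIfTI volumes via nibabel.  Masks are NIfTI
(uint8) or per-slice PNG overlays.  Cohorts are plain CSV.  JSON reports
are written with sorted keys and a trailing newline so identical runs
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import dicomio
from .errors import MixedSeriesError, ValidationError
from .volume import CTVolume, LungMask

_REQUIRED_COHORT_COLUMNS = [
    "id",
    "subtype",
    "cam_extent_pct",
    "warrick_reader1",
    "warrick_reader2",
    "warrick_mean",
    "fvc_pct",
    "fev1_pct",
    "dlco_pct",
]


# ---------------------------------------------------------------------------
# DICOM series


def write_ct_series(volume: CTVolume, out_dir: Path | str, series_tag: str = "ctild") -> list[Path]:
    """Write a volume as one DICOM file per axial slice.

    Slice positions run superior -> inferior (decreasing patient z with
    increasing slice index).  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dz, dy, dx = volume.spacing_mm
    series_uid = dicomio.deterministic_uid(
        series_tag,
        volume.shape,
        volume.spacing_mm,
        hashlib.sha256(volume.voxels.tobytes()).hexdigest(),
    )
    paths = []
    for z in range(volume.shape[0]):
        path = out_dir / f"slice_{z:04d}.dcm"
        dicomio.write_slice(
            path,
            volume.voxels[z],
            series_uid=series_uid,
            instance_number=z + 1,
            position=(0.0, 0.0, -z * dz),
            pixel_spacing=(dy, dx),
            slice_thickness=1.25,
        )
        paths.append(path)
    return paths


def read_ct_series(path: Path | str) -> CTVolume:
    """Read a CT volume from a DICOM series directory or a NIfTI file.

    DICOM slices are sorted by patient-z position (superior first)
    regardless of file naming; mixed series raise
    :class:`~ctild.errors.MixedSeriesError`.
    """
    path = Path(path)
    if path.is_file():
        return read_volume_nifti(path)
    files = sorted(path.glob("*.dcm"))
    if not files:
        raise ValidationError(f"{path}: no .dcm files found")
    slices = [dicomio.read_slice(f) for f in files]
    uids = {s.series_uid for s in slices}
    if len(uids) > 1:
        raise MixedSeriesError(
            f"{path}: directory holds {len(uids)} distinct series"
        )
    slices.sort(key=lambda s: -s.position[2])  # superior (high z) first
    hu = np.stack([s.hu for s in slices])
    zs = np.array([s.position[2] for s in slices])
    if len(zs) > 1:
        gaps = np.abs(np.diff(zs))
        if np.ptp(gaps) > 1e-3:
            raise ValidationError(f"{path}: non-uniform slice spacing")
        dz = float(gaps[0])
    else:
        dz = slices[0].slice_thickness or 1.0
    dy, dx = slices[0].pixel_spacing
    return CTVolume.from_hu(hu, (dz, dy, dx))


# ---------------------------------------------------------------------------
# NIfTI

def _nifti_affine(spacing_mm) -> np.ndarray:
    dz, dy, dx = spacing_mm
    return np.diag([dx, dy, dz, 1.0])


def write_volume_nifti(volume: CTVolume, path: Path | str) -> None:
    # store as (x, y, z) per NIfTI convention; int16 HU
    data = np.transpose(volume.voxels, (2, 1, 0)).astype(np.int16)
    img = nib.Nifti1Image(data, _nifti_affine(volume.spacing_mm))
    nib.save(img, str(path))


def read_volume_nifti(path: Path | str) -> CTVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3-D NIfTI volume")
    zooms = img.header.get_zooms()[:3]
    voxels = np.transpose(data, (2, 1, 0))
    return CTVolume.from_hu(voxels, (float(zooms[2]), float(zooms[1]), float(zooms[0])))


def write_mask_nifti(mask: LungMask, path: Path | str, spacing_mm=(1.0, 1.0, 1.0)) -> None:
    data = np.transpose(mask.mask.astype(np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _nifti_affine(spacing_mm)), str(path))


def read_mask_nifti(path: Path | str) -> LungMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3-D NIfTI mask")
    return LungMask(mask=np.transpose(data, (2, 1, 0)) > 0)


def write_mask_overlays(volume: CTVolume, mask: LungMask, out_dir: Path | str) -> list[Path]:
    """Per-slice PNG overlays (lung mask tinted red over the CT slice)."""
    import imageio.v3 as iio

    mask.check_aligned(volume)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = -1024.0, 400.0
    paths = []
    for z in range(volume.shape[0]):
        grey = np.clip((volume.voxels[z] - lo) / (hi - lo), 0, 1)
        rgb = np.stack([grey, grey, grey], axis=-1)
        rgb[mask.mask[z], 0] = 1.0
        path = out_dir / f"overlay_{z:04d}.png"
        iio.imwrite(path, (rgb * 255).astype(np.uint8))
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# tables and reports


def write_cohort_csv(table: pd.DataFrame, path: Path | str) -> None:
    missing = [c for c in _REQUIRED_COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    table.to_csv(path, index=False, lineterminator="\n", float_format="%.6f")


def read_cohort_csv(path: Path | str) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: cohort CSV missing columns {missing}")
    return table


def write_json_report(payload: dict, path: Path | str) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=False)
    Path(path).write_text(text + "\n")
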