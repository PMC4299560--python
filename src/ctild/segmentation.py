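"""Semiautomatic threshold-based lung segmentation.

The parenchyma is isolated by keeping voxels inside an inclusive HU band
(default [-1024, -200]), discarding connected components that touch the
axial image border (exterior air), applying a minimum-size filter, and
removing the tracheal air column.  Remaining non-parenchymal structures
(vessels, large bronchi near the hilum) can be cut out with per-slice
polygonal manual exclusions, mirroring the minimal-intervention editing
step of the reference workflow.

Connectivity is 2-D (8-connected) within each slice by default because
wide inter-slice spacing makes 3-D adjacency unreliable; a 26-connected
3-D mode is available for contiguous volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure, morphology

from .errors import ConfigurationError, EmptySegmentationError, ValidationError
from .volume import CTVolume, LungMask

Polygon = Sequence[tuple[float, float]]  # (row, col) vertices
SliceRegion = tuple[int, Polygon]

DEFAULT_LUNG_BAND = (-1024, -200)


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the threshold segmentation.

    ``lung_band`` is the inclusive HU interval of lung parenchyma;
    ``closing_radius`` > 0 enables per-slice morphological closing that
    fills vessel holes smaller than that radius (the returned mask then
    may exceed the raw thresholded set).
    """

    lung_band: tuple[int, int] = DEFAULT_LUNG_BAND
    min_component_voxels: int = 20
    connectivity: str = "2d"  # "2d" (8-connected in-plane) or "3d" (26-connected)
    closing_radius: int = 0
    central_fraction: float = 1.0 / 3.0  # trachea search box, per axis
    manual_exclusions: tuple[SliceRegion, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        lo, hi = self.lung_band
        if lo > hi:
            raise ConfigurationError(f"lung band lower bound {lo} exceeds upper {hi}")
        if self.min_component_voxels < 1:
            raise ConfigurationError("min_component_voxels must be >= 1")
        if self.connectivity not in ("2d", "3d"):
            raise ConfigurationError(f"unknown connectivity {self.connectivity!r}")
        if not 0 < self.central_fraction <= 1:
            raise ConfigurationError("central_fraction must lie in (0, 1]")


def band_mask(volume: CTVolume, band: tuple[int, int]) -> np.ndarray:
    """Voxels whose HU lies inside the inclusive band."""
    return (volume.voxels >= band[0]) & (volume.voxels <= band[1])


def _central_box(shape2d: tuple[int, int], frac: float) -> tuple[slice, slice]:
    ny, nx = shape2d
    dy, dx = ny * frac, nx * frac
    return (
        slice((ny - dy) / 2.0, (ny + dy) / 2.0),
        slice((nx - dx) / 2.0, (nx + dx) / 2.0),
    )


def _in_central_box(centroid: tuple[float, float], shape2d: tuple[int, int], frac: float) -> bool:
    (ys, xs) = _central_box(shape2d, frac)
    return ys.start <= centroid[0] <= ys.stop and xs.start <= centroid[1] <= xs.stop


def _label_slices(in_band: np.ndarray) -> np.ndarray:
    labels = np.zeros(in_band.shape, dtype=np.int32)
    for z in range(in_band.shape[0]):
        labels[z] = measure.label(in_band[z], connectivity=2)
    return labels


def _drop_border_and_small_2d(
    in_band: np.ndarray, min_voxels: int
) -> np.ndarray:
    kept = np.zeros_like(in_band)
    for z in range(in_band.shape[0]):
        labels = measure.label(in_band[z], connectivity=2)
        if labels.max() == 0:
            continue
        border = np.unique(
            np.concatenate(
                [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
            )
        )
        counts = np.bincount(labels.ravel())
        good = np.ones(labels.max() + 1, dtype=bool)
        good[0] = False
        good[border[border > 0]] = False
        good[counts < min_voxels] = False
        kept[z] = good[labels]
    return kept


def _remove_trachea_2d(mask: np.ndarray, frac: float) -> np.ndarray:
    """Remove the air column: seeded on central components of the most
    superior non-empty slice, propagated downward by in-plane footprint
    overlap (components keeping a centroid inside the central box)."""
    out = mask.copy()
    z0 = _first_nonempty(mask)
    if z0 < 0:
        return out
    prev_footprint: np.ndarray | None = None
    for z in range(z0, mask.shape[0]):
        sl = out[z]
        if not sl.any():
            prev_footprint = None
            continue
        labels = measure.label(sl, connectivity=2)
        footprint = np.zeros(sl.shape, dtype=bool)
        for region in measure.regionprops(labels):
            if not _in_central_box(region.centroid, sl.shape, frac):
                continue
            comp = labels == region.label
            seeded = z == z0
            overlaps = prev_footprint is not None and (comp & prev_footprint).any()
            if seeded or overlaps:
                footprint |= comp
        if footprint.any():
            out[z] &= ~footprint
            prev_footprint = footprint
        else:
            prev_footprint = None
    return out


def _first_nonempty(mask: np.ndarray) -> int:
    for z in range(mask.shape[0]):
        if mask[z].any():
            return z
    return -1


def _segment_3d(in_band: np.ndarray, params: SegmentationParams) -> np.ndarray:
    labels = measure.label(in_band, connectivity=3)
    if labels.max() == 0:
        return np.zeros_like(in_band)
    border_ids = np.unique(
        np.concatenate(
            [
                labels[:, 0, :].ravel(),
                labels[:, -1, :].ravel(),
                labels[:, :, 0].ravel(),
                labels[:, :, -1].ravel(),
            ]
        )
    )
    counts = np.bincount(labels.ravel())
    good = np.ones(labels.max() + 1, dtype=bool)
    good[0] = False
    good[border_ids[border_ids > 0]] = False
    good[counts < params.min_component_voxels] = False
    kept = good[labels]

    # trachea: component present in the most superior non-empty slice with an
    # in-plane centroid inside the central box
    relabel = measure.label(kept, connectivity=3)
    z0 = _first_nonempty(kept)
    if z0 >= 0:
        for lab in np.unique(relabel[z0])[1:]:
            comp_slice = relabel[z0] == lab
            ys, xs = np.nonzero(comp_slice)
            centroid = (float(ys.mean()), float(xs.mean()))
            if _in_central_box(centroid, comp_slice.shape, params.central_fraction):
                kept[relabel == lab] = False
    return kept


def segment_lungs(volume: CTVolume, params: SegmentationParams | None = None) -> LungMask:
    """Threshold-based lung segmentation.

    Raises :class:`~ctild.errors.EmptySegmentationError` when no candidate
    lung component survives the band and size filters.
    """
    params = params or SegmentationParams()
    params.validate()

    in_band = band_mask(volume, params.lung_band)
    if params.connectivity == "2d":
        kept = _drop_border_and_small_2d(in_band, params.min_component_voxels)
        kept = _remove_trachea_2d(kept, params.central_fraction)
    else:
        kept = _segment_3d(in_band, params)

    if params.closing_radius > 0:
        footprint = morphology.disk(params.closing_radius)
        for z in range(kept.shape[0]):
            kept[z] = morphology.binary_closing(kept[z], footprint)

    if not kept.any():
        raise EmptySegmentationError(
            f"no lung component found with band {params.lung_band} and "
            f"min_component_voxels={params.min_component_voxels}"
        )

    mask = LungMask(
        mask=kept,
        provenance={
            "lung_band": list(params.lung_band),
            "min_component_voxels": params.min_component_voxels,
            "connectivity": params.connectivity,
            "closing_radius": params.closing_radius,
            "manual_exclusions": [
                [s, [list(map(float, v)) for v in poly]]
                for s, poly in params.manual_exclusions
            ],
        },
    )
    if params.manual_exclusions:
        mask = apply_manual_exclusions(mask, params.manual_exclusions)
    return mask


def rasterize_polygon(shape2d: tuple[int, int], polygon: Polygon) -> np.ndarray:
    """Pixels whose centers fall inside (or on the boundary of) the polygon."""
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValidationError("polygon needs at least 3 (row, col) vertices")
    return measure.grid_points_in_poly(shape2d, verts)


def apply_manual_exclusions(
    mask: LungMask, regions: Sequence[SliceRegion]
) -> LungMask:
    """Remove per-slice polygonal regions from a mask.

    Each region is ``(slice_index, [(row, col), ...])``.  The voxel count is
    non-increasing; a polygon on a nonexistent slice raises
    :class:`~ctild.errors.ValidationError`.
    """
    out = mask.mask.copy()
    nz = out.shape[0]
    for slice_idx, polygon in regions:
        if not 0 <= slice_idx < nz:
            raise ValidationError(
                f"exclusion polygon on slice {slice_idx}, volume has {nz} slices"
            )
        inside = rasterize_polygon(out.shape[1:], polygon)
        out[slice_idx] &= ~inside
    provenance = dict(mask.provenance)
    applied = provenance.get("exclusions_applied", 0)
    provenance["exclusions_applied"] = applied + len(regions)
    return LungMask(mask=out, provenance=provenance)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap between two binary masks of identical shape."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("masks must share a shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
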