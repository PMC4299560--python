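"""Synthetic chest-CT phantoms with known ground truth.

A phantom is a stack of sparse axial sections (thin slices at wide
inter-slice spacing, as on clinical HRCT) holding four attenuation
compartments: exterior/tracheal air, normal lung parenchyma, fibrotic
lung, and soft tissue (body, vessels).  The generator records the exact
lung mask and the exact fibrotic fraction before noise is added, so the
segmentation and densitometry stages can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .volume import CTVolume, LungMask

# compartment labels in the ground-truth grid
_EXTERIOR = 0
_BODY = 1
_NORMAL_LUNG = 2
_FIBROTIC_LUNG = 3
_TRACHEA = 4
_VESSEL = 5

DEFAULT_HU_MEANS = {
    "air": -1000.0,
    "normal_lung": -850.0,
    "fibrotic": -600.0,
    "soft_tissue": 40.0,
}


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid, in voxel units: ``center`` and ``radii`` are
    (slice, row, column) triples."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]


@dataclass(frozen=True)
class LungGeometry:
    """Two ellipsoidal half-lungs, a cylindrical trachea stub connected to
    the most superior slice, and optional small vessel stubs inside the
    lungs (soft-tissue density, excluded from the truth mask)."""

    left_lung: Ellipsoid
    right_lung: Ellipsoid
    body_radii_frac: tuple[float, float] = (0.44, 0.46)  # (row, col) as grid fraction
    trachea_center: tuple[float, float] | None = None  # (row, col); None = centered
    trachea_radius: float = 3.0
    trachea_depth: int = 0  # number of superior slices holding the trachea
    vessel_radius: float = 1.0
    n_vessel_slices: int = 2

    @classmethod
    def default(cls, grid_shape: tuple[int, int, int]) -> "LungGeometry":
        nz, ny, nx = grid_shape
        rz = max(nz / 2.0 - 1.0, 1.0)
        ry, rx = 0.28 * ny, 0.17 * nx
        cz = (nz - 1) / 2.0
        cy = 0.52 * ny
        return cls(
            left_lung=Ellipsoid((cz, cy, 0.28 * nx), (rz, ry, rx)),
            right_lung=Ellipsoid((cz, cy, 0.72 * nx), (rz, ry, rx)),
            trachea_center=(0.50 * ny, 0.50 * nx),
            trachea_radius=max(2.0, 0.03 * nx),
            trachea_depth=max(2, nz // 3),
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic phantom.

    ``hu_params`` maps compartment name to (mean, sd); ``noise_sd`` is
    additional global additive noise.  Noise is added before rounding to
    the integer HU convention.
    """

    grid_shape: tuple[int, int, int] = (12, 96, 96)
    spacing_mm: tuple[float, float, float] = (7.0, 0.7, 0.7)
    lung_geometry: LungGeometry | None = None
    target_fibrotic_fraction: float = 0.0
    hu_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: (v, 0.0) for k, v in DEFAULT_HU_MEANS.items()}
    )
    noise_sd: float = 0.0
    seed: int = 0

    def geometry(self) -> LungGeometry:
        return self.lung_geometry or LungGeometry.default(self.grid_shape)

    def validate(self) -> None:
        if not 0.0 <= self.target_fibrotic_fraction <= 1.0:
            raise ConfigurationError(
                f"target_fibrotic_fraction must lie in [0, 1], "
                f"got {self.target_fibrotic_fraction}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        means = {k: v[0] for k, v in self.hu_params.items()}
        required = set(DEFAULT_HU_MEANS)
        if set(means) != required:
            raise ConfigurationError(
                f"hu_params must define exactly the compartments {sorted(required)}"
            )
        if not (
            means["air"] < means["normal_lung"] < means["fibrotic"] < means["soft_tissue"]
        ):
            raise ConfigurationError(
                "compartment means must be ordered air < normal lung < fibrotic "
                "< soft tissue"
            )
        geo = self.geometry()
        nz, ny, nx = self.grid_shape
        for name, ell in (("left_lung", geo.left_lung), ("right_lung", geo.right_lung)):
            for axis, (c, r, n) in enumerate(zip(ell.center, ell.radii, (nz, ny, nx))):
                if c - r < -0.5 or c + r > n - 0.5:
                    raise ConfigurationError(
                        f"{name} exceeds the grid along axis {axis}: "
                        f"center {c}, radius {r}, size {n}"
                    )
        if geo.trachea_depth > nz:
            raise ConfigurationError("trachea deeper than the grid")


@dataclass(frozen=True)
class PhantomVolume:
    """Generated phantom: image, ground-truth mask and the exact fibrotic
    percentage recorded before noise was added."""

    volume: CTVolume
    truth_mask: LungMask
    truth_fibrotic_fraction: float
    labels: np.ndarray


def _ellipsoid_mask(shape: tuple[int, int, int], ell: Ellipsoid) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = ell.center
    rz, ry, rx = ell.radii
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _build_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    nz, ny, nx = spec.grid_shape
    geo = spec.geometry()
    labels = np.full(spec.grid_shape, _EXTERIOR, dtype=np.uint8)

    # body: elliptical cylinder of soft tissue spanning all slices
    ry = geo.body_radii_frac[0] * ny
    rx = geo.body_radii_frac[1] * nx
    yy, xx = np.ogrid[:ny, :nx]
    body2d = ((yy - (ny - 1) / 2.0) / ry) ** 2 + ((xx - (nx - 1) / 2.0) / rx) ** 2 <= 1.0
    labels[:, body2d] = _BODY

    lungs = _ellipsoid_mask(spec.grid_shape, geo.left_lung) | _ellipsoid_mask(
        spec.grid_shape, geo.right_lung
    )
    labels[lungs] = _NORMAL_LUNG

    # trachea: air column connected to slice 0, centered in the axial plane
    if geo.trachea_depth > 0:
        tc = geo.trachea_center or ((ny - 1) / 2.0, (nx - 1) / 2.0)
        circle = ((yy - tc[0]) ** 2 + (xx - tc[1]) ** 2) <= geo.trachea_radius**2
        if (labels[: geo.trachea_depth, circle] == _NORMAL_LUNG).any():
            raise ConfigurationError(
                "trachea stub intersects a lung ellipsoid; adjust the geometry"
            )
        labels[: geo.trachea_depth, circle] = _TRACHEA

    # vessel stubs: short soft-tissue rods inside each lung, middle slices
    if geo.vessel_radius > 0 and geo.n_vessel_slices > 0:
        mid = nz // 2
        for ell in (geo.left_lung, geo.right_lung):
            cy_l, cx_l = ell.center[1], ell.center[2]
            half_len = max(2, int(0.3 * ell.radii[2]))
            rod = (np.abs(yy - cy_l) <= geo.vessel_radius) & (
                np.abs(xx - cx_l) <= half_len
            )
            for k in range(geo.n_vessel_slices):
                s = mid + k
                if 0 <= s < nz:
                    sl = labels[s]
                    sl[rod & (sl == _NORMAL_LUNG)] = _VESSEL

    # fibrotic assignment: exact count of lung voxels, chosen at random
    lung_idx = np.flatnonzero(labels == _NORMAL_LUNG)
    n_lung = lung_idx.size
    if n_lung == 0:
        raise ConfigurationError("geometry produced no lung voxels")
    k = int(round(spec.target_fibrotic_fraction * n_lung))
    if k > 0:
        chosen = rng.choice(lung_idx, size=k, replace=False)
        labels.ravel()[chosen] = _FIBROTIC_LUNG
    return labels


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Generate a phantom volume with ground truth.

    Identical spec (including seed) yields a byte-identical volume.  Raises
    :class:`~ctild.errors.ConfigurationError` when the geometry does not fit
    the grid or the spec is otherwise invalid.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = _build_labels(spec, rng)

    truth = (labels == _NORMAL_LUNG) | (labels == _FIBROTIC_LUNG)
    n_lung = int(truth.sum())
    n_fibrotic = int((labels == _FIBROTIC_LUNG).sum())
    truth_ff = 100.0 * n_fibrotic / n_lung

    compartment_of = {
        _EXTERIOR: "air",
        _TRACHEA: "air",
        _BODY: "soft_tissue",
        _VESSEL: "soft_tissue",
        _NORMAL_LUNG: "normal_lung",
        _FIBROTIC_LUNG: "fibrotic",
    }
    hu = np.empty(spec.grid_shape, dtype=np.float64)
    for lab, name in compartment_of.items():
        mean, sd = spec.hu_params[name]
        sel = labels == lab
        if sd > 0:
            hu[sel] = mean + sd * rng.standard_normal(int(sel.sum()))
        else:
            hu[sel] = mean
    if spec.noise_sd > 0:
        hu += spec.noise_sd * rng.standard_normal(spec.grid_shape)

    volume = CTVolume.from_hu(hu, spec.spacing_mm)
    mask = LungMask(mask=truth, provenance={"source": "phantom", "seed": spec.seed})
    return PhantomVolume(
        volume=volume,
        truth_mask=mask,
        truth_fibrotic_fraction=truth_ff,
        labels=labels,
    )
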