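"""Core image containers: CT volumes and binary lung masks.

Conventions
-----------
* Voxel arrays are indexed ``(slice, row, column)``, 0-based, with slice 0
  the most superior section.
* Attenuation is stored as signed 16-bit integers in Hounsfield units (HU),
  clamped below at -1024 HU.
* ``spacing_mm`` is per-axis physical spacing ``(slice, row, column)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ConfigurationError

HU_FLOOR = -1024


@dataclass(frozen=True)
class CTVolume:
    """A 3-D grid of attenuation values in HU with physical voxel spacing."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ConfigurationError("CT volume must be a non-empty 3-D grid")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError(f"invalid voxel spacing {self.spacing_mm!r}")
        if self.voxels.min() < HU_FLOOR:
            raise ConfigurationError(
                f"HU values below {HU_FLOOR} must be clamped before construction"
            )

    @classmethod
    def from_hu(
        cls, hu: np.ndarray, spacing_mm: tuple[float, float, float]
    ) -> "CTVolume":
        """Build a volume from (possibly float) HU values, clamping and
        rounding to the stored integer convention."""
        voxels = np.rint(np.asarray(hu)).astype(np.int16)
        voxels = np.maximum(voxels, HU_FLOOR)
        return cls(voxels=voxels, spacing_mm=tuple(float(s) for s in spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class LungMask:
    """Binary voxel mask aligned to a :class:`CTVolume`.

    ``provenance`` records the parameters and exclusions that produced the
    mask so a segmentation can be reproduced from its output.
    """

    mask: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask.ndim != 3:
            raise ConfigurationError("lung mask must be 3-D")
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def check_aligned(self, volume: CTVolume) -> None:
        if self.shape != volume.shape:
            raise ConfigurationError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )
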