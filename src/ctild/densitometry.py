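"""Density-mask quantities on a segmented lung.

The fibrosis fraction is the percentage of in-band lung voxels whose
attenuation exceeds the nonfibrotic threshold:

    FF = 100 * (N_total - N_nonfibrotic) / N_total

with N_total the masked voxels in the total lung band [-1024, -200] HU and
N_nonfibrotic those in [-1024, -700] HU.  Boundary semantics are fixed: a
voxel at exactly -700 HU counts as nonfibrotic, so the fibrotic band is the
half-open interval (-700, -200].  Histogram descriptors (mean lung
attenuation, skewness, kurtosis) are computed over the same N_total voxels;
kurtosis is un-excess (normal distribution = 3) unless requested otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, UndefinedFractionError, ZeroVarianceError
from .volume import CTVolume, LungMask


@dataclass(frozen=True)
class DensityBands:
    """HU bands of the density mask: shared lower bound, nonfibrotic upper
    threshold, and total-band upper bound."""

    lower: int = -1024
    nonfibrotic_upper: int = -700
    total_upper: int = -200

    def validate(self) -> None:
        if not self.lower <= self.nonfibrotic_upper <= self.total_upper:
            raise ConfigurationError(
                f"bands must be ordered lower <= nonfibrotic_upper <= total_upper, "
                f"got ({self.lower}, {self.nonfibrotic_upper}, {self.total_upper})"
            )

    @property
    def total_band(self) -> tuple[int, int]:
        return (self.lower, self.total_upper)

    @property
    def nonfibrotic_band(self) -> tuple[int, int]:
        return (self.lower, self.nonfibrotic_upper)


@dataclass(frozen=True)
class DensitometryResult:
    fibrosis_fraction_pct: float
    mla_hu: float
    skewness: float | None
    kurtosis: float | None
    n_total_voxels: int
    n_nonfibrotic_voxels: int
    volume_ml: float

    def to_dict(self) -> dict:
        return {
            "fibrosis_fraction_pct": self.fibrosis_fraction_pct,
            "mla_hu": self.mla_hu,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "n_total_voxels": self.n_total_voxels,
            "n_nonfibrotic_voxels": self.n_nonfibrotic_voxels,
            "volume_ml": self.volume_ml,
        }


def _masked_in_band(
    volume: CTVolume, mask: LungMask, bands: DensityBands
) -> np.ndarray:
    mask.check_aligned(volume)
    bands.validate()
    values = volume.voxels[mask.mask]
    return values[(values >= bands.lower) & (values <= bands.total_upper)]


def _moments(values: np.ndarray) -> tuple[float, float | None, float | None]:
    """Mean, skewness m3/m2^(3/2) and Pearson kurtosis m4/m2^2 (normal = 3)
    from population moments.  Skewness/kurtosis are None at zero variance."""
    mean = float(values.mean())
    centered = values.astype(np.float64) - mean
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        return mean, None, None
    m3 = float(np.mean(centered**3))
    m4 = float(np.mean(centered**4))
    return mean, m3 / m2**1.5, m4 / m2**2


def fibrosis_fraction(
    volume: CTVolume,
    mask: LungMask,
    bands: DensityBands | None = None,
    excess_kurtosis: bool = False,
) -> DensitometryResult:
    """Fibrosis fraction and histogram descriptors for a segmented lung.

    Raises :class:`~ctild.errors.UndefinedFractionError` when no masked voxel
    lies in the total band (no silent zero).  Skewness/kurtosis are ``None``
    for a constant in-band histogram; the fraction and MLA are still valid.
    """
    bands = bands or DensityBands()
    values = _masked_in_band(volume, mask, bands)
    n_total = int(values.size)
    if n_total == 0:
        raise UndefinedFractionError(
            f"no masked voxel in total band [{bands.lower}, {bands.total_upper}]"
        )
    n_nonfibrotic = int((values <= bands.nonfibrotic_upper).sum())
    ff = 100.0 * (n_total - n_nonfibrotic) / n_total
    mla, skew, kurt = _moments(values)
    if kurt is not None and excess_kurtosis:
        kurt -= 3.0
    return DensitometryResult(
        fibrosis_fraction_pct=ff,
        mla_hu=mla,
        skewness=skew,
        kurtosis=kurt,
        n_total_voxels=n_total,
        n_nonfibrotic_voxels=n_nonfibrotic,
        volume_ml=n_total * volume.voxel_volume_mm3 / 1000.0,
    )


def histogram_descriptors(
    volume: CTVolume,
    mask: LungMask,
    bands: DensityBands | None = None,
    excess_kurtosis: bool = False,
) -> tuple[float, float, float]:
    """(MLA, skewness, kurtosis) over masked in-band voxels.

    Raises :class:`~ctild.errors.ZeroVarianceError` (carrying the MLA) when
    fewer than two distinct HU values are present.
    """
    bands = bands or DensityBands()
    values = _masked_in_band(volume, mask, bands)
    if values.size == 0:
        raise UndefinedFractionError(
            f"no masked voxel in total band [{bands.lower}, {bands.total_upper}]"
        )
    mla, skew, kurt = _moments(values)
    if skew is None or kurt is None:
        raise ZeroVarianceError(
            "constant HU histogram: skewness and kurtosis are undefined",
            mla_hu=mla,
        )
    if excess_kurtosis:
        kurt -= 3.0
    return mla, skew, kurt
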