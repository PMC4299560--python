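import numpy as np
import pytest
from scipy import stats as sps

from ctild.densitometry import DensityBands, fibrosis_fraction, histogram_descriptors
from ctild.errors import (
    ConfigurationError,
    UndefinedFractionError,
    ZeroVarianceError,
)
from ctild.phantom import PhantomSpec, generate_phantom
from ctild.segmentation import segment_lungs
from ctild.volume import LungMask

from conftest import full_mask, make_volume, uniform_volume


class TestFibrosisFraction:
    def test_all_nonfibrotic_gives_zero(self):
        vol = uniform_volume(-850)
        res = fibrosis_fraction(vol, full_mask(vol))
        assert res.fibrosis_fraction_pct == 0.0

    def test_all_fibrotic_gives_hundred(self):
        vol = uniform_volume(-600)
        res = fibrosis_fraction(vol, full_mask(vol))
        assert res.fibrosis_fraction_pct == 100.0

    def test_direct_voxel_count_30_percent(self):
        values = np.full(1000, -850)
        values[:300] = -600
        vol = make_volume(values.reshape(1, 10, 100))
        res = fibrosis_fraction(vol, full_mask(vol))
        assert res.fibrosis_fraction_pct == pytest.approx(30.0)
        assert res.n_total_voxels == 1000
        assert res.n_nonfibrotic_voxels == 700

    def test_boundary_voxel_at_700_counts_nonfibrotic(self):
        vol = uniform_volume(-700)
        res = fibrosis_fraction(vol, full_mask(vol))
        assert res.fibrosis_fraction_pct == 0.0

    def test_voxel_just_above_700_counts_fibrotic(self):
        vol = uniform_volume(-699)
        res = fibrosis_fraction(vol, full_mask(vol))
        assert res.fibrosis_fraction_pct == 100.0

    def test_out_of_band_voxels_ignored(self):
        values = np.concatenate([np.full(500, -850), np.full(500, 40)])
        vol = make_volume(values.reshape(1, 10, 100))
        res = fibrosis_fraction(vol, full_mask(vol))
        assert res.n_total_voxels == 500
        assert res.fibrosis_fraction_pct == 0.0

    def test_empty_band_raises_not_silent_zero(self):
        vol = uniform_volume(40)  # soft tissue only
        with pytest.raises(UndefinedFractionError):
            fibrosis_fraction(vol, full_mask(vol))

    def test_band_decomposition_exact(self, small_phantom):
        mask = segment_lungs(small_phantom.volume)
        res = fibrosis_fraction(small_phantom.volume, mask)
        values = small_phantom.volume.voxels[mask.mask]
        fibrotic = int(((values > -700) & (values <= -200)).sum())
        assert res.n_total_voxels == res.n_nonfibrotic_voxels + fibrotic

    def test_monotonicity_raising_voxel_hu(self):
        values = np.full(100, -850)
        vol_lo = make_volume(values.reshape(1, 10, 10))
        values2 = values.copy()
        values2[0] = -600
        vol_hi = make_volume(values2.reshape(1, 10, 10))
        ff_lo = fibrosis_fraction(vol_lo, full_mask(vol_lo)).fibrosis_fraction_pct
        ff_hi = fibrosis_fraction(vol_hi, full_mask(vol_hi)).fibrosis_fraction_pct
        assert ff_hi >= ff_lo

    def test_recovery_on_noise_free_phantom_exact(self, small_phantom):
        mask = segment_lungs(small_phantom.volume)
        res = fibrosis_fraction(small_phantom.volume, mask)
        assert res.fibrosis_fraction_pct == small_phantom.truth_fibrotic_fraction

    def test_recovery_under_noise_within_tolerance(self):
        errors = []
        for seed in range(20):
            ph = generate_phantom(
                PhantomSpec(target_fibrotic_fraction=0.5, noise_sd=30.0, seed=seed)
            )
            mask = segment_lungs(ph.volume)
            ff = fibrosis_fraction(ph.volume, mask).fibrosis_fraction_pct
            errors.append(abs(ff - ph.truth_fibrotic_fraction))
        assert max(errors) <= 1.5

    def test_volume_ml(self):
        vol = uniform_volume(-850, shape=(1, 10, 10))  # spacing 7 x 0.7 x 0.7 mm
        res = fibrosis_fraction(vol, full_mask(vol))
        assert res.volume_ml == pytest.approx(100 * 7.0 * 0.7 * 0.7 / 1000.0)

    def test_invalid_bands_rejected(self):
        vol = uniform_volume(-850)
        with pytest.raises(ConfigurationError, match="ordered"):
            fibrosis_fraction(vol, full_mask(vol), DensityBands(-1024, -200, -700))


class TestHistogramDescriptors:
    def test_symmetric_two_point_histogram(self):
        values = np.concatenate([np.full(50, -900), np.full(50, -800)])
        vol = make_volume(values.reshape(1, 10, 10))
        mla, skew, kurt = histogram_descriptors(vol, full_mask(vol))
        assert mla == pytest.approx(-850.0)
        assert skew == pytest.approx(0.0)
        assert kurt == pytest.approx(1.0)  # two-point symmetric: m4/m2^2 = 1

    def test_truncated_normal_kurtosis_monte_carlo(self):
        # oracle: exact moments of the truncated normal the draws come from
        lo, hi, mu, sd = -1024, -200, -600.0, 120.0
        a, b = (lo - mu) / sd, (hi - mu) / sd
        rng = np.random.default_rng(0)
        draws = sps.truncnorm.rvs(a, b, loc=mu, scale=sd, size=10**6, random_state=rng)
        vol = make_volume(draws.reshape(100, 100, 100))
        _, _, kurt = histogram_descriptors(vol, full_mask(vol))
        expected = float(sps.truncnorm.stats(a, b, moments="k")) + 3.0
        assert kurt == pytest.approx(expected, abs=0.05)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(-700, 80, size=4096).clip(-1024, -200)
        vol = make_volume(draws.reshape(1, 64, 64))
        values = vol.voxels[full_mask(vol).mask].astype(float)
        mla, skew, kurt = histogram_descriptors(vol, full_mask(vol))
        assert mla == pytest.approx(values.mean())
        assert skew == pytest.approx(float(sps.skew(values)))
        assert kurt == pytest.approx(float(sps.kurtosis(values, fisher=False)))

    def test_single_voxel_mask_zero_variance_error(self):
        vol = uniform_volume(-850)
        mask = np.zeros(vol.shape, dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ZeroVarianceError) as excinfo:
            histogram_descriptors(vol, LungMask(mask=mask))
        assert excinfo.value.mla_hu == pytest.approx(-850.0)

    def test_constant_histogram_error_retains_mla(self):
        vol = uniform_volume(-600)
        with pytest.raises(ZeroVarianceError) as excinfo:
            histogram_descriptors(vol, full_mask(vol))
        assert excinfo.value.mla_hu == pytest.approx(-600.0)

    def test_excess_flag_shifts_by_three(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(-700, 50, size=1000).clip(-1024, -200)
        vol = make_volume(draws.reshape(1, 25, 40))
        _, _, kurt = histogram_descriptors(vol, full_mask(vol))
        _, _, kurt_excess = histogram_descriptors(
            vol, full_mask(vol), excess_kurtosis=True
        )
        assert kurt_excess == pytest.approx(kurt - 3.0)

    def test_mla_within_band(self, small_phantom):
        mask = segment_lungs(small_phantom.volume)
        res = fibrosis_fraction(small_phantom.volume, mask)
        assert -1024 <= res.mla_hu <= -200
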