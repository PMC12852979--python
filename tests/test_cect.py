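import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import dice
from ligcect.cect import (
    DiffusionSeries,
    bulk_partition,
    dilution_error,
    fit_uptake,
    hu_calibrate,
    segment_tissue,
    uptake_model,
)
from ligcect.io import CTVolume, ValidationError
from ligcect.synthetic import gen_diffusion_series

HSETTINGS = settings(max_examples=25, deadline=None, derandomize=True)


def _toy_volume(water=1000.0, air=0.0, tissue=1500.0):
    grid = np.full((4, 16, 16), air, dtype=np.float32)
    grid[:, 2:6, 2:6] = water
    grid[:, 8:14, 8:14] = tissue
    water_roi = np.zeros_like(grid, bool)
    water_roi[:, 3:5, 3:5] = True
    air_roi = np.zeros_like(grid, bool)
    air_roi[:, 0:2, 12:16] = True
    return CTVolume(intensities=grid, water_roi=water_roi, air_roi=air_roi)


class TestCalibration:
    def test_water_to_zero_air_to_minus_1000(self):
        cal = hu_calibrate(_toy_volume())
        assert cal.intensities[cal.water_roi].mean() == pytest.approx(0.0, abs=1e-3)
        assert cal.intensities[cal.air_roi].mean() == pytest.approx(-1000.0, abs=1e-3)

    def test_already_calibrated_fixed_point(self):
        cal = hu_calibrate(_toy_volume(water=0.0, air=-1000.0, tissue=500.0))
        np.testing.assert_allclose(
            cal.intensities,
            _toy_volume(water=0.0, air=-1000.0, tissue=500.0).intensities,
            atol=1e-3,
        )

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            hu_calibrate(_toy_volume(water=5.0, air=5.0))

    def test_phantom_region_means_restored(self, clean_phantom):
        _, series, truth = clean_phantom
        cal = hu_calibrate(series[-1])
        fasc = cal.intensities[truth.fascicle_mask].mean()
        ifm = cal.intensities[truth.ifm_mask].mean()
        # 72 h is far past equilibrium for tau = 5.38 h
        assert abs(fasc - truth.mu_fascicle_HU) < 0.5
        assert abs(ifm - truth.mu_ifm_HU) < 0.5


class TestTissueSegmentation:
    def test_noiseless_phantom_dice_vs_shrunk_truth(self, clean_phantom):
        native, _, truth = clean_phantom
        from ligcect.cect import _disk_erode

        seg = segment_tissue(hu_calibrate(native))
        shrunk = np.stack(
            [_disk_erode(truth.tissue_mask[z], 10) for z in range(truth.tissue_mask.shape[0])]
        )
        assert dice(seg.mask, shrunk) >= 0.99

    def test_all_background_volume_rejected(self):
        rng = np.random.default_rng(0)
        grid = rng.normal(-1000, 20, size=(4, 64, 64)).astype(np.float32)
        vol = CTVolume(intensities=grid, calibrated=True)
        with pytest.raises(ValidationError):
            segment_tissue(vol)

    def test_seed_recorded_and_deterministic(self, noisy_phantom):
        native, _, _ = noisy_phantom
        cal = hu_calibrate(native)
        a = segment_tissue(cal, seed=3)
        b = segment_tissue(cal, seed=3)
        assert a.seed == 3
        np.testing.assert_array_equal(a.mask, b.mask)


class TestBulkPartition:
    @staticmethod
    def _flat_volume(value, timepoint=None):
        grid = np.full((2, 8, 8), value, dtype=np.float32)
        return CTVolume(intensities=grid, calibrated=True, timepoint_h=timepoint)

    def test_partition_arithmetic(self):
        native = self._flat_volume(50.0)
        late = self._flat_volume(450.0, timepoint=8.0)
        mask = np.ones((2, 8, 8), bool)
        series = bulk_partition(native, [late], mask, bath_hu=800.0)
        assert series.partition[0] == pytest.approx(0.5)

    def test_native_timepoint_partition_zero(self):
        native = self._flat_volume(50.0)
        same = self._flat_volume(50.0, timepoint=0.75)
        mask = np.ones((2, 8, 8), bool)
        series = bulk_partition(native, [same], mask, bath_hu=800.0)
        assert series.partition[0] == pytest.approx(0.0)

    def test_nonpositive_bath_rejected(self):
        native = self._flat_volume(50.0)
        late = self._flat_volume(450.0, timepoint=8.0)
        with pytest.raises(ValidationError, match="bath"):
            bulk_partition(native, [late], np.ones((2, 8, 8), bool), bath_hu=0.0)

    def test_affine_recalibration_invariance(self):
        # applying one affine map to tissue, native and bath leaves the
        # partition unchanged when the offset cancels in both differences
        native = self._flat_volume(50.0)
        late = self._flat_volume(450.0, timepoint=8.0)
        mask = np.ones((2, 8, 8), bool)
        base = bulk_partition(native, [late], mask, bath_hu=800.0)
        a = 2.5
        native2 = self._flat_volume(50.0 * a)
        late2 = self._flat_volume(450.0 * a, timepoint=8.0)
        scaled = bulk_partition(native2, [late2], mask, bath_hu=800.0 * a)
        assert scaled.partition[0] == pytest.approx(base.partition[0], rel=1e-12)


class TestUptakeFit:
    def test_zero_residual_exact_recovery(self):
        t = np.array([0.5, 1.0, 2.0, 4.0])
        series = DiffusionSeries(t, uptake_model(t, 1.0, 1.0))
        fit = fit_uptake(series)
        assert fit.Pmax == pytest.approx(1.0, rel=1e-6)
        assert fit.tau_h == pytest.approx(1.0, rel=1e-6)

    def test_curve_at_tau_is_63_percent_of_pmax(self):
        series = gen_diffusion_series(2.49, 5.38, [3, 8, 22, 46, 72])
        fit = fit_uptake(series)
        assert fit(fit.tau_h) == pytest.approx(0.632 * fit.Pmax, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match="3 timepoints"):
            fit_uptake(DiffusionSeries(np.array([1.0, 2.0]), np.array([0.5, 0.7])))

    @given(
        pmax=st.floats(0.05, 20.0),
        tau=st.floats(0.2, 30.0),  # identifiable from the 0.75-72 h grid
        scale=st.floats(0.1, 10.0),
    )
    @HSETTINGS
    def test_scale_equivariance_and_zero_noise_recovery(self, pmax, tau, scale):
        t = np.array([0.75, 1.5, 3.0, 5.0, 8.0, 22.0, 72.0])
        base = fit_uptake(DiffusionSeries(t, uptake_model(t, pmax, tau)))
        assert base.Pmax == pytest.approx(pmax, rel=1e-6)
        assert base.tau_h == pytest.approx(tau, rel=1e-6)
        scaled = fit_uptake(DiffusionSeries(t, scale * uptake_model(t, pmax, tau)))
        assert scaled.Pmax == pytest.approx(scale * pmax, rel=1e-6)
        assert scaled.tau_h == pytest.approx(tau, rel=1e-5)


class TestDilutionError:
    def test_zero_partition(self):
        assert dilution_error(0.0) == 0.0

    def test_reference_value(self):
        assert dilution_error(2.49, 100) == pytest.approx(0.0249)

    def test_monotone_vanishing_with_ratio(self):
        errs = [dilution_error(2.49, r) for r in (10, 100, 1000, 1e6)]
        assert all(a > b for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-5

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValidationError):
            dilution_error(1.0, 0)
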