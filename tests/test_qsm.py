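import numpy as np
import pytest
from numpy.fft import fftn

from ironmap.forward import EchoSeries, FieldMap, forward_field, simulate_mgre
from ironmap.geometry import AcquisitionGeometry
from ironmap.phantom import make_phantom
from ironmap.qsm import (
    ReconConfig,
    fit_field,
    invert_dipole,
    reference_qsm,
    reliability_mask,
    remove_background,
    unwrap_phase,
)


def _single_echo_series(phase, geometry=None):
    geometry = geometry or AcquisitionGeometry(
        grid_shape=phase.shape, echo_times_ms=(1.68,)
    )
    return EchoSeries(
        magnitude=np.ones(phase.shape + (1,)),
        phase=phase[..., None],
        geometry=geometry,
    )


class TestUnwrapPhase:
    def test_constant_phase_unchanged_up_to_constant(self):
        phase = np.full((32, 32, 32), 0.5)
        series = _single_echo_series(phase)
        unw = unwrap_phase(series, np.ones(phase.shape, bool))[..., 0]
        dev = unw - phase
        assert np.ptp(dev) < 1e-9

    def test_six_pi_ramp_recovered(self):
        n = 48
        ramp = 6 * np.pi * (np.arange(n) / (n - 1))[:, None, None] * np.ones((n, n, n))
        wrapped = np.angle(np.exp(1j * ramp))
        series = _single_echo_series(wrapped)
        unw = unwrap_phase(series, np.ones((n, n, n), bool))[..., 0]
        dev = unw - ramp
        dev -= 2 * np.pi * np.round(np.median(dev) / (2 * np.pi))
        assert np.abs(dev).max() < 0.01

    def test_wrap_free_phase_identity(self):
        rng = np.random.default_rng(0)
        from scipy import ndimage

        smooth = ndimage.gaussian_filter(rng.standard_normal((32, 32, 32)), 4)
        smooth *= 2.0 / np.abs(smooth).max()  # stays well inside (-pi, pi)
        series = _single_echo_series(smooth)
        unw = unwrap_phase(series, np.ones(smooth.shape, bool))[..., 0]
        dev = unw - smooth
        assert np.ptp(dev) < 1e-9

    def test_matches_path_following_oracle(self):
        """Independent oracle: scikit-image's 3-D path-following unwrapper."""
        from scipy import ndimage
        from skimage.restoration import unwrap_phase as sk_unwrap

        rng = np.random.default_rng(1)
        true = ndimage.gaussian_filter(rng.standard_normal((32, 32, 32)), 3)
        true *= 12.0 / np.abs(true).max()  # several wraps
        wrapped = np.angle(np.exp(1j * true))
        series = _single_echo_series(wrapped)
        ours = unwrap_phase(series, np.ones(true.shape, bool))[..., 0]
        oracle = np.asarray(sk_unwrap(wrapped))
        diff = ours - oracle
        diff -= 2 * np.pi * np.round(np.median(diff) / (2 * np.pi))
        assert np.abs(diff).max() < 1e-6

    def test_empty_mask_errors(self):
        series = _single_echo_series(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="mask"):
            unwrap_phase(series, np.zeros((8, 8, 8), bool))


class TestFitField:
    def test_exact_frequency_recovered(self, small_geometry):
        te = small_geometry.echo_times_s
        shape = small_geometry.grid_shape
        phase = 2 * np.pi * 25.0 * te * np.ones(shape + (te.size,))
        series = EchoSeries(
            magnitude=np.ones(shape + (te.size,)),
            phase=np.angle(np.exp(1j * phase)),
            geometry=small_geometry,
        )
        fm = fit_field(phase, series)
        assert np.allclose(fm.frequency, 25.0, atol=1e-9)
        assert np.allclose(fm.residual, 0.0, atol=1e-9)

    def test_zero_phase_gives_zero_field(self, small_geometry):
        shape = small_geometry.grid_shape + (small_geometry.n_echoes,)
        series = EchoSeries(
            magnitude=np.ones(shape), phase=np.zeros(shape),
            geometry=small_geometry,
        )
        fm = fit_field(np.zeros(shape), series)
        assert np.allclose(fm.frequency, 0.0)
        assert np.allclose(fm.residual, 0.0)

    def test_fewer_than_two_echoes_errors(self):
        geom = AcquisitionGeometry(grid_shape=(4, 4, 4), echo_times_ms=(1.68,))
        series = EchoSeries(
            magnitude=np.ones((4, 4, 4, 1)), phase=np.zeros((4, 4, 4, 1)),
            geometry=geom,
        )
        with pytest.raises(ValueError, match="echo"):
            fit_field(np.zeros((4, 4, 4, 1)), series)

    def test_noiseless_phantom_round_trip(self, phantom, phantom_field,
                                          noiseless_series):
        """simulate -> unwrap -> fit recovers the field to < 1e-6 Hz RMSE."""
        unw = unwrap_phase(noiseless_series, phantom.brain_mask)
        fm = fit_field(unw, noiseless_series)
        err = (fm.frequency - phantom_field.frequency)[phantom.brain_mask]
        assert np.sqrt((err**2).mean()) < 1e-6


class TestReliabilityMask:
    def test_noiseless_data_keeps_everything(self, phantom, noiseless_series):
        unw = unwrap_phase(noiseless_series, phantom.brain_mask)
        fm = fit_field(unw, noiseless_series)
        rel = reliability_mask(fm, ReconConfig(), phantom.brain_mask)
        assert np.array_equal(rel, phantom.brain_mask & fm.mask)

    def test_infinite_threshold_is_identity(self, phantom, noiseless_series):
        unw = unwrap_phase(noiseless_series, phantom.brain_mask)
        fm = fit_field(unw, noiseless_series)
        cfg = ReconConfig(residual_threshold_rad=np.inf)
        rel = reliability_mask(fm, cfg, phantom.brain_mask)
        assert np.array_equal(rel, phantom.brain_mask & fm.mask)

    def test_single_echo_corruption_is_rejected(self, phantom, noiseless_series):
        voxel = (48, 48, 48)
        phase = noiseless_series.phase.copy()
        phase[voxel + (5,)] = np.angle(np.exp(1j * (phase[voxel + (5,)] + 3.0)))
        corrupted = EchoSeries(
            magnitude=noiseless_series.magnitude, phase=phase,
            geometry=noiseless_series.geometry,
        )
        unw = unwrap_phase(corrupted, phantom.brain_mask)
        fm = fit_field(unw, corrupted)
        rel = reliability_mask(fm, ReconConfig(), phantom.brain_mask)
        assert not rel[voxel]
        excluded = phantom.brain_mask & fm.mask & ~rel
        assert excluded.sum() == 1


class TestRemoveBackground:
    def test_zero_field_stays_zero(self, phantom, geometry):
        fm = FieldMap(frequency=np.zeros(geometry.grid_shape),
                      mask=phantom.brain_mask)
        local = remove_background(fm, phantom.brain_mask, ReconConfig(), geometry)
        assert np.allclose(local.frequency, 0.0)
        assert local.mask.sum() > 0.5 * phantom.brain_mask.sum()

    def test_external_sources_are_removed(self, phantom, geometry):
        chi = np.where(~phantom.brain_mask, 9000.0, 0.0)
        fm_full = forward_field(chi, geometry)
        fm = FieldMap(frequency=fm_full.frequency, mask=phantom.brain_mask)
        local = remove_background(fm, phantom.brain_mask, ReconConfig(), geometry)
        rms_in = np.sqrt((fm.frequency[local.mask] ** 2).mean())
        rms_out = np.sqrt((local.frequency[local.mask] ** 2).mean())
        assert rms_out < 0.05 * rms_in

    def test_interior_source_is_preserved(self, phantom, geometry):
        # preservation measured as the least-squares projection of the local
        # field onto the input field over the ROI (the plain ROI mean of an
        # interior source's field nearly cancels and is numerically unstable)
        chi = np.where(phantom.roi_mask("putamen"), 50.0, 0.0)
        fm_full = forward_field(chi, geometry)
        fm = FieldMap(frequency=fm_full.frequency, mask=phantom.brain_mask)
        local = remove_background(fm, phantom.brain_mask, ReconConfig(), geometry)
        roi = phantom.roi_mask("putamen") & local.mask
        projection = ((local.frequency[roi] * fm.frequency[roi]).sum()
                      / (fm.frequency[roi] ** 2).sum())
        assert projection > 0.8

    def test_mask_smaller_than_kernel_errors(self, small_geometry):
        mask = np.zeros(small_geometry.grid_shape, bool)
        mask[12, 12, 12] = True
        fm = FieldMap(frequency=np.zeros(small_geometry.grid_shape), mask=mask)
        with pytest.raises(ValueError, match="SMV"):
            remove_background(fm, mask, ReconConfig(), small_geometry)


class TestInvertDipole:
    def test_zero_field_gives_zero_chi(self, small_geometry):
        mask = np.ones(small_geometry.grid_shape, bool)
        fm = FieldMap(frequency=np.zeros(small_geometry.grid_shape), mask=mask)
        chi = invert_dipole(fm, small_geometry, ReconConfig())
        assert np.allclose(chi.chi, 0.0)

    def test_linearity(self, small_geometry):
        rng = np.random.default_rng(2)
        mask = np.ones(small_geometry.grid_shape, bool)
        freq = rng.normal(size=small_geometry.grid_shape)
        one = invert_dipole(FieldMap(frequency=freq, mask=mask),
                            small_geometry, ReconConfig())
        two = invert_dipole(FieldMap(frequency=2 * freq, mask=mask),
                            small_geometry, ReconConfig())
        assert np.allclose(two.chi, 2 * one.chi, atol=1e-9)

    def test_invalid_threshold_errors(self, small_geometry):
        mask = np.ones(small_geometry.grid_shape, bool)
        fm = FieldMap(frequency=np.zeros(small_geometry.grid_shape), mask=mask)
        for delta in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                invert_dipole(fm, small_geometry, ReconConfig(tkd_threshold=delta))

    def test_identity_on_well_conditioned_spectrum(self, small_geometry):
        """invert o forward is the identity where |D(k)| >= delta."""
        from ironmap.forward import dipole_kernel

        rng = np.random.default_rng(3)
        chi_true = rng.normal(size=small_geometry.grid_shape)
        fm_raw = forward_field(chi_true, small_geometry, pad_factor=1)
        mask = np.ones(small_geometry.grid_shape, bool)
        cfg = ReconConfig(tkd_threshold=0.2)
        chi_est = invert_dipole(
            FieldMap(frequency=fm_raw.frequency, mask=mask), small_geometry, cfg
        )
        d = dipole_kernel(small_geometry).values
        keep = np.abs(d) >= cfg.tkd_threshold
        spec_true = fftn(chi_true)
        spec_est = fftn(chi_est.chi)
        assert np.allclose(spec_est[keep], spec_true[keep], atol=1e-6 * np.abs(spec_true).max())


class TestReferenceQsm:
    def test_zero_mean_and_idempotent(self, small_geometry):
        from ironmap.qsm import SusceptibilityMap

        rng = np.random.default_rng(4)
        mask = np.ones(small_geometry.grid_shape, bool)
        chi = SusceptibilityMap(chi=rng.normal(5, 2, small_geometry.grid_shape),
                                mask=mask)
        once = reference_qsm(chi)
        twice = reference_qsm(once)
        assert abs(once.chi[mask].mean()) < 1e-6
        assert np.allclose(once.chi, twice.chi, atol=1e-12)

    def test_reference_none_is_identity(self, small_geometry):
        from ironmap.qsm import SusceptibilityMap

        chi = SusceptibilityMap(
            chi=np.full(small_geometry.grid_shape, 3.0),
            mask=np.ones(small_geometry.grid_shape, bool),
        )
        assert reference_qsm(chi, reference="none") is chi

    def test_referenced_chi_invariant_to_constant_field_offset(self, small_geometry):
        rng = np.random.default_rng(5)
        mask = np.ones(small_geometry.grid_shape, bool)
        freq = rng.normal(size=small_geometry.grid_shape)
        cfg = ReconConfig()
        a = reference_qsm(invert_dipole(FieldMap(frequency=freq, mask=mask),
                                        small_geometry, cfg))
        b = reference_qsm(invert_dipole(FieldMap(frequency=freq + 7.5, mask=mask),
                                        small_geometry, cfg))
        assert np.allclose(a.chi, b.chi, atol=1e-8)
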