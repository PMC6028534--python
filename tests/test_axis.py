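"""Axis tracing, preprocessing, FWHM and radial intensity profiles."""

import numpy as np
import pytest
from scipy import ndimage

from condensinmap import axis as axmod, synthetic_data as syn
from condensinmap.stack import ImageStack

ISO20 = (20.0, 20.0, 20.0)


class TestPreprocess:
    def test_injected_interslice_drift_removed(self):
        """40-nm lateral drift per slice leaves < 5-nm residual."""
        from skimage.registration import phase_cross_correlation

        base = syn.render_tube(
            syn.straight_axis(2000.0) + np.array([300.0, 600.0, 300.0]),
            150.0, (30, 60, 140), ISO20,
        )
        drifted = base.data.copy()
        for zi in range(15, drifted.shape[0]):  # one 40-nm drift event
            drifted[zi] = ndimage.shift(base.data[zi], (2.0, 0.0), order=1)
        pre = axmod.preprocess_stack(ImageStack(drifted, ISO20))
        residuals = []
        for zi in range(10, 20):
            shift, _, _ = phase_cross_correlation(
                pre.data[zi - 1], pre.data[zi], upsample_factor=50, normalization=None
            )
            residuals.append(shift)
        assert np.abs(residuals).max() * 20.0 < 5.0

    def test_isotropic_input_interpolation_is_identity(self):
        rng = np.random.default_rng(0)
        data = rng.random((6, 20, 20))
        pre = axmod.preprocess_stack(
            ImageStack(data, ISO20), drift_correct=False, smooth_sigma_vox=0.0
        )
        assert np.allclose(pre.data, data)
        assert pre.voxel_size_nm == ISO20

    def test_constant_image_unchanged_by_smoothing(self):
        data = np.full((6, 20, 20), 7.0)
        pre = axmod.preprocess_stack(ImageStack(data, ISO20), drift_correct=False)
        assert np.allclose(pre.data, 7.0)

    def test_z_interpolation_reaches_isotropy(self):
        data = np.zeros((5, 16, 16))
        data[2] = 1.0
        pre = axmod.preprocess_stack(
            ImageStack(data, (140.0, 20.0, 20.0)), drift_correct=False,
            smooth_sigma_vox=0.0,
        )
        assert pre.voxel_size_nm == (20.0, 20.0, 20.0)
        assert pre.data.shape[0] == 29  # 4 * 140 / 20 + 1

    def test_single_slice_warns_and_skips_drift(self):
        data = np.random.default_rng(1).random((1, 16, 16))
        with pytest.warns(UserWarning, match="single-slice"):
            axmod.preprocess_stack(ImageStack(data, ISO20))


class TestTraceAxis:
    def test_straight_tube_length(self, straight_tube_20nm):
        _, mask = straight_tube_20nm
        trace = axmod.trace_axis(mask, 20.0)
        assert trace.length_nm == pytest.approx(2000.0, abs=40.0)

    def test_quarter_circle_arc_length(self, quarter_circle_tube_20nm):
        _, mask = quarter_circle_tube_20nm
        trace = axmod.trace_axis(mask, 20.0)
        assert trace.length_nm == pytest.approx(np.pi * 2000.0 / 2.0, rel=0.03)

    def test_isotropic_blob_rejected(self):
        blob = np.zeros((30, 40, 40), bool)
        blob[5:25, 10:30, 10:30] = True
        with pytest.raises(ValueError, match="dominant axis"):
            axmod.trace_axis(blob, 20.0)

    def test_end_trim_shortens_axis(self, straight_tube_20nm):
        _, mask = straight_tube_20nm
        full = axmod.trace_axis(mask, 20.0)
        trimmed = axmod.trace_axis(mask, 20.0, end_trim_nm=400.0)
        assert trimmed.length_nm == pytest.approx(full.length_nm - 800.0, abs=60.0)

    def test_length_invariant_under_rotation(self):
        """45-degree in-plane rotation changes the traced length < 2%."""
        axis0 = syn.straight_axis(4000.0)
        m_axis = syn.tube_mask(
            axis0 + np.array([300.0, 400.0, 300.0]), 200.0, (30, 40, 240), ISO20
        )
        th = np.pi / 4
        rot = np.array(
            [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
        )
        rotated = (axis0 - axis0.mean(0)) @ rot.T + np.array([300.0, 1700.0, 1700.0])
        m_rot = syn.tube_mask(rotated, 200.0, (30, 170, 170), ISO20)
        l0 = axmod.trace_axis(m_axis, 20.0).length_nm
        l1 = axmod.trace_axis(m_rot, 20.0).length_nm
        assert l1 == pytest.approx(l0, rel=0.02)

    def test_consecutive_spacing_near_target(self, straight_tube_20nm):
        _, mask = straight_tube_20nm
        trace = axmod.trace_axis(mask, 20.0)
        seg = np.linalg.norm(np.diff(trace.points, axis=0), axis=1)
        assert np.all(seg <= 1.5 * trace.spacing_nm)
        assert np.all(seg >= 0.5 * trace.spacing_nm)


class TestFwhm:
    def test_gaussian_tube_analytic_fwhm(self, gaussian_tube_100nm):
        _, stack, mask = gaussian_tube_100nm
        trace = axmod.trace_axis(mask, 20.0)
        wp = axmod.compute_fwhm_profile(stack, trace, lateral_extent_nm=800.0)
        assert wp.mean_fwhm_nm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 100.0, rel=0.02)

    def test_wide_tube_matches_chromatid_scale(self):
        """sigma = 467 nm gives the ~1.1-µm pooled chromatid width."""
        vox = (40.0, 40.0, 40.0)
        axis = syn.straight_axis(5000.0) + np.array([2000.0, 2000.0, 1000.0])
        stack = syn.render_tube(axis, 467.0, (100, 100, 180), vox)
        mask = syn.tube_mask(axis, 500.0, (100, 100, 180), vox)
        trace = axmod.trace_axis(mask, 40.0)
        wp = axmod.compute_fwhm_profile(stack, trace, lateral_extent_nm=1600.0)
        assert wp.mean_fwhm_nm == pytest.approx(1100.0, rel=0.02)

    def test_intensity_scale_invariance(self, gaussian_tube_100nm):
        _, stack, mask = gaussian_tube_100nm
        trace = axmod.trace_axis(mask, 20.0)
        w1 = axmod.compute_fwhm_profile(stack, trace, lateral_extent_nm=800.0)
        doubled = ImageStack(2.0 * stack.data, stack.voxel_size_nm)
        w2 = axmod.compute_fwhm_profile(doubled, trace, lateral_extent_nm=800.0)
        assert np.allclose(w1.fwhm_per_window_nm, w2.fwhm_per_window_nm)

    def test_background_offset_tolerated(self, gaussian_tube_100nm):
        """Offsets below ~10% of peak shift the FWHM < 2% after the
        tail-median background subtraction."""
        _, stack, mask = gaussian_tube_100nm
        trace = axmod.trace_axis(mask, 20.0)
        w1 = axmod.compute_fwhm_profile(stack, trace, lateral_extent_nm=800.0)
        offset = ImageStack(
            stack.data + 0.08 * stack.data.max(), stack.voxel_size_nm
        )
        w2 = axmod.compute_fwhm_profile(offset, trace, lateral_extent_nm=800.0)
        assert w2.mean_fwhm_nm == pytest.approx(w1.mean_fwhm_nm, rel=0.02)

    def test_width_ratio_recovery(self):
        """Two tubes with sigma ratio 1.5 yield FWHM ratio within 5%."""
        widths = []
        for sigma in (150.0, 225.0):
            axis = syn.straight_axis(4000.0) + np.array([600.0, 1200.0, 600.0])
            shape = (60, 120, 260)
            stack = syn.render_tube(axis, sigma, shape, ISO20)
            mask = syn.tube_mask(axis, 300.0, shape, ISO20)
            trace = axmod.trace_axis(mask, 20.0)
            widths.append(
                axmod.compute_fwhm_profile(stack, trace, lateral_extent_nm=1000.0).mean_fwhm_nm
            )
        assert widths[1] / widths[0] == pytest.approx(1.5, rel=0.05)

    def test_axis_shorter_than_window_errors(self, straight_tube_20nm):
        _, mask = straight_tube_20nm
        trace = axmod.trace_axis(mask, 20.0)
        with pytest.raises(ValueError, match="shorter than one window"):
            axmod.compute_fwhm_profile(
                ImageStack(mask.astype(float), ISO20), trace, window_nm=5000.0
            )


class TestRadialProfile:
    def _tube_and_axis(self, sigma):
        axis = syn.straight_axis(3000.0) + np.array([500.0, 800.0, 300.0])
        shape = (50, 80, 180)
        stack = syn.render_tube(axis, sigma, shape, ISO20)
        mask = syn.tube_mask(axis, 250.0, shape, ISO20)
        return stack, axmod.trace_axis(mask, 20.0)

    def test_gaussian_tube_90pct_containment(self):
        """90% of a radially symmetric Gaussian (sigma 170 nm) lies
        within r = sigma * sqrt(2 ln 10) ~ 365 nm (730-nm diameter)."""
        stack, trace = self._tube_and_axis(170.0)
        rp = axmod.compute_radial_profile(
            stack, trace, chromatid_width_nm=1600.0, lateral_extent_nm=900.0
        )
        r90 = rp.containment_radius(0.9)
        assert 2 * r90 == pytest.approx(2 * 2.146 * 170.0, rel=0.05)
        assert rp.intensity[0] == 1.0

    def test_containment_monotone_in_quantile(self):
        stack, trace = self._tube_and_axis(170.0)
        rp = axmod.compute_radial_profile(
            stack, trace, chromatid_width_nm=1600.0, lateral_extent_nm=900.0
        )
        rs = [rp.containment_radius(q) for q in (0.3, 0.5, 0.7, 0.9)]
        assert np.all(np.diff(rs) > 0)

    def test_symmetric_input_symmetrization_identity(self):
        stack, trace = self._tube_and_axis(150.0)
        rp = axmod.compute_radial_profile(
            stack, trace, chromatid_width_nm=1600.0, lateral_extent_nm=900.0
        )
        expected = np.exp(-0.5 * (rp.radius_nm / 150.0) ** 2)
        assert np.allclose(rp.intensity, expected, atol=0.03)

    def test_peripheral_population_produces_shoulders(self):
        """A narrow axial population plus peripheral satellite tubes
        yields more mass beyond 1.5 sigma than a single Gaussian."""
        axis = syn.straight_axis(3000.0) + np.array([500.0, 800.0, 300.0])
        shape = (50, 80, 180)
        central = syn.render_tube(axis, 120.0, shape, ISO20).data
        sat1 = syn.render_tube(axis + np.array([0.0, 350.0, 0.0]), 100.0, shape, ISO20).data
        sat2 = syn.render_tube(axis - np.array([0.0, 350.0, 0.0]), 100.0, shape, ISO20).data
        stack = ImageStack(central + 0.3 * (sat1 + sat2), ISO20)
        mask = syn.tube_mask(axis, 250.0, shape, ISO20)
        trace = axmod.trace_axis(mask, 20.0)
        rp = axmod.compute_radial_profile(
            stack, trace, chromatid_width_nm=1600.0, lateral_extent_nm=900.0
        )
        # single-Gaussian reference from the half-max radius of the core
        r_half = np.interp(-0.5, -rp.intensity, rp.radius_nm)
        sigma_fit = r_half / np.sqrt(2 * np.log(2))
        tail = rp.radius_nm > 2.0 * sigma_fit
        gauss_tail = np.exp(-0.5 * (rp.radius_nm[tail] / sigma_fit) ** 2)
        assert rp.intensity[tail].sum() > 1.5 * gauss_tail.sum()

    def test_window_larger_than_image_errors(self):
        stack, trace = self._tube_and_axis(150.0)
        with pytest.raises(ValueError, match="window larger"):
            axmod.compute_radial_profile(
                stack, trace, chromatid_width_nm=50000.0, lateral_extent_nm=900.0
            )
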