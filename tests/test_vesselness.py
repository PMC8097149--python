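"""Frangi machinery: Hessian oracles, closed-form responses, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vrsquant.vesselness import (
    VesselnessParams,
    hessian_2d,
    multiscale_vesselness,
    vesselness_2d,
)
from vrsquant.volume import ImageVolume, ROIMask

SPACING = (0.75, 0.75)


class TestHessian:
    def test_constant_slice_gives_zero(self):
        h = hessian_2d(np.full((32, 32), 7.0), 0.75, SPACING)
        for comp in h:
            assert np.allclose(comp, 0.0, atol=1e-5)

    @pytest.mark.parametrize("sigma_mm", [0.75, 1.0, 1.5])
    @pytest.mark.parametrize("a_mm", [1.5, 2.5])
    def test_analytic_gaussian_ridge(self, sigma_mm, a_mm):
        """Hxx at the crest of exp(-x^2/2a^2) matches scale-space closed form.

        Smoothing a Gaussian ridge of width a with G_sigma gives amplitude
        a/sqrt(a^2+s^2) and width sqrt(a^2+s^2); the normalised second
        derivative at the crest is -s^2 * a / (a^2+s^2)^(3/2).
        """
        n = 81
        x = (np.arange(n) - n // 2) * SPACING[0]
        slice2d = np.tile(np.exp(-(x**2) / (2 * a_mm**2))[:, None], (1, n))
        hxx, _, _ = hessian_2d(slice2d, sigma_mm, SPACING)
        expected = -(sigma_mm**2) * a_mm / (a_mm**2 + sigma_mm**2) ** 1.5
        assert hxx[n // 2, n // 2] == pytest.approx(expected, rel=0.02)

    def test_mixed_derivative_symmetric(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(48, 48)).astype(np.float32)
        from scipy import ndimage as ndi

        sig = (1.0 / SPACING[0], 1.0 / SPACING[1])
        xy = ndi.gaussian_filter(ndi.gaussian_filter(img, (sig[0], 0), order=(1, 0)),
                                 (0, sig[1]), order=(0, 1))
        yx = ndi.gaussian_filter(ndi.gaussian_filter(img, (0, sig[1]), order=(0, 1)),
                                 (sig[0], 0), order=(1, 0))
        assert np.allclose(xy, yx, atol=5e-4)

    def test_under_resolved_scale_warns(self):
        with pytest.warns(UserWarning, match="under-resolved"):
            hessian_2d(np.zeros((8, 8)), 0.1, SPACING)

    def test_agrees_with_skimage_hessian(self):
        """Independent cross-check against skimage's Hessian machinery.

        skimage factors the second derivative into two cascaded
        first-order filters at sigma/sqrt(2); at well-resolved scales the
        two discretisations coincide away from the borders.
        """
        from skimage.feature import hessian_matrix

        rng = np.random.default_rng(1)
        img = rng.normal(size=(64, 64)).astype(np.float64)
        sigma, sp = 2.0, (1.0, 1.0)  # unit spacing so conventions align
        hxx, hxy, hyy = hessian_2d(img, sigma, sp, gamma_norm=0.0)
        hrr, hrc, hcc = hessian_matrix(
            img, sigma=sigma, order="rc", use_gaussian_derivatives=True
        )
        interior = (slice(20, -20), slice(20, -20))
        scale = np.abs(hrr[interior]).max()
        for mine, ref in ((hxx, hrr), (hxy, hrc), (hyy, hcc)):
            assert np.allclose(mine[interior], ref[interior], atol=0.02 * scale)


class TestVesselnessClosedForm:
    def test_ideal_tube_value(self):
        """lambda1 = 0, lambda2 = -2c gives V = 1 - e^-2 ~ 0.8647."""
        shape = (8, 8)
        hxx = np.full(shape, -4.0)
        hxy = np.zeros(shape)
        hyy = np.zeros(shape)
        # auto c: S = 4 everywhere -> c = 2 -> lambda2 = -2c holds
        v = vesselness_2d(hxx, hxy, hyy, VesselnessParams())
        assert v == pytest.approx(1.0 - np.exp(-2.0), abs=1e-6)

    def test_bright_polarity_suppresses_dark_tube(self):
        shape = (8, 8)
        v = vesselness_2d(np.full(shape, 4.0), np.zeros(shape), np.zeros(shape),
                          VesselnessParams())
        assert np.all(v == 0.0)

    def test_blob_suppression_factor(self):
        """Isotropic blob carries the e^-2 blobness factor with beta=0.5."""
        shape = (4, 4)
        c = 1.0
        lam = -1.0
        params = VesselnessParams(beta=0.5, c_mode="fixed", c_value=c)
        v_blob = vesselness_2d(np.full(shape, lam), np.zeros(shape), np.full(shape, lam), params)
        s2 = 2 * lam**2
        expected = np.exp(-2.0) * (1 - np.exp(-s2 / (2 * c**2)))
        assert v_blob == pytest.approx(expected, abs=1e-9)
        # a tube with the same |lambda2| responds strictly more
        v_tube = vesselness_2d(np.full(shape, lam), np.zeros(shape), np.zeros(shape), params)
        assert np.all(v_tube > v_blob)

    def test_blank_slice_is_zero_not_error(self):
        z = np.zeros((6, 6))
        v = vesselness_2d(z, z, z, VesselnessParams())
        assert np.all(v == 0.0)

    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(2)
        hxx, hxy, hyy = rng.normal(size=(3, 64, 64))
        v = vesselness_2d(hxx, hxy, hyy, VesselnessParams())
        assert v.min() >= 0.0 and v.max() <= 1.0


def _tube_volume(angle_deg, shape=(64, 64, 3), a_mm=0.45, contrast=90.0):
    """Analytic bright tube with Gaussian cross-section at a given angle."""
    nx, ny, nz = shape
    x = (np.arange(nx) - nx / 2) * 0.75
    y = (np.arange(ny) - ny / 2) * 0.75
    X, Y = np.meshgrid(x, y, indexing="ij")
    t = np.radians(angle_deg)
    d = -np.sin(t) * X + np.cos(t) * Y  # distance from the tube axis
    sl = 100.0 + contrast * np.exp(-(d**2) / (2 * a_mm**2))
    vol = np.full(shape, 100.0, dtype=np.float32)
    vol[:, :, 1] = sl
    return ImageVolume(vol, (0.75, 0.75, 4.0))


class TestMultiscale:
    def test_single_scale_reduces_to_composition(self, rendered_subject):
        from vrsquant.masking import supraventricular_roi

        _, vol, truth, _ = rendered_subject
        roi = supraventricular_roi(truth, vol.spacing)
        params = VesselnessParams(scales_mm=(0.75,))
        ms = multiscale_vesselness(vol, roi, params)
        from scipy import ndimage as ndi

        z = roi.z_level + 1
        dil = ndi.binary_dilation(roi.mask)[:, :, z]
        hxx, hxy, hyy = hessian_2d(vol.data[:, :, z], 0.75, vol.spacing[:2])
        hxx, hxy, hyy = (np.where(dil, h, 0.0) for h in (hxx, hxy, hyy))
        direct = vesselness_2d(hxx, hxy, hyy, params)
        inside = roi.mask[:, :, z]
        assert np.allclose(ms[:, :, z][inside], direct[inside], atol=5e-4)

    def test_rotation_invariant_peak_response(self):
        roi = ROIMask(np.ones((64, 64, 3), bool), 0)
        peaks = {}
        for ang in (0.0, 37.0):
            v = multiscale_vesselness(_tube_volume(ang), roi, VesselnessParams())
            peaks[ang] = float(v[:, :, 1].max())
        assert peaks[37.0] == pytest.approx(peaks[0.0], rel=0.05)

    def test_max_over_scales_dominates_single_scales(self, rendered_subject):
        from vrsquant.masking import supraventricular_roi

        _, vol, truth, _ = rendered_subject
        roi = supraventricular_roi(truth, vol.spacing)
        full = multiscale_vesselness(vol, roi, VesselnessParams(scales_mm=(0.5, 0.75)))
        for s in (0.5, 0.75):
            single = multiscale_vesselness(vol, roi, VesselnessParams(scales_mm=(s,)))
            assert np.all(full >= single - 5e-4)

    def test_zero_outside_dilated_roi(self, rendered_subject):
        from scipy import ndimage as ndi
        from vrsquant.masking import supraventricular_roi

        _, vol, truth, _ = rendered_subject
        roi = supraventricular_roi(truth, vol.spacing)
        v = multiscale_vesselness(vol, roi, VesselnessParams())
        outside = ~ndi.binary_dilation(roi.mask)
        assert np.all(v[outside] == 0.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(shift=st.floats(-50.0, 50.0))
def test_intensity_shift_invariance(shift):
    """Adding a constant to the slice leaves the vesselness unchanged."""
    rng = np.random.default_rng(5)
    base = rng.normal(100.0, 10.0, size=(32, 32)).astype(np.float64)
    params = VesselnessParams()
    v0 = vesselness_2d(*hessian_2d(base, 0.75, SPACING), params)
    v1 = vesselness_2d(*hessian_2d(base + shift, 0.75, SPACING), params)
    assert np.allclose(v0, v1, atol=5e-4)
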