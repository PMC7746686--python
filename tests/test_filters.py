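import numpy as np
import pytest

from octarep.filters import (
    BrtParams,
    GaborParams,
    HessianParams,
    apply_filter,
    bayesian_residual_enhance,
    gabor_argmax_orientation,
    gabor_enhance,
    hessian_vesselness,
)
from octarep.types import EnFaceAngiogram


def _snr(px):
    signal = px[59:61].mean() - px[:40].mean()
    return signal / px[:40].std()


class TestHessian:
    def test_constant_image_gives_zero(self, flat_image):
        assert hessian_vesselness(flat_image).pixels.max() == 0.0

    def test_bar_response_peaks_on_centerline(self, bar_image):
        """A 30 um bright bar yields max ridge response on its centre row and
        a negligible response three bar-widths away."""
        resp = hessian_vesselness(bar_image).pixels
        col = resp[:, 100]
        assert col.argmax() in (59, 60)
        assert col[59] > 10 * col[59 + 18]  # 3 bar-widths (18 px) away

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        px = np.clip(0.3 + 0.2 * rng.standard_normal((128, 128)), 0, 1)
        px[60:63, 20:110] = 0.95
        img = EnFaceAngiogram(px, 15.0, 15.0)
        rot = EnFaceAngiogram(np.rot90(px).copy(), 15.0, 15.0)
        a = np.rot90(hessian_vesselness(img).pixels)
        b = hessian_vesselness(rot).pixels
        interior = (slice(10, -10), slice(10, -10))
        assert np.allclose(a[interior], b[interior], atol=1e-10)

    def test_dark_ridge_suppressed(self):
        px = np.full((100, 100), 0.8)
        px[49:51, :] = 0.1  # dark bar: lambda2 > 0 branch
        resp = hessian_vesselness(EnFaceAngiogram(px, 15.0, 15.0)).pixels
        assert resp[49:51, 40:60].max() == 0.0

    def test_invalid_params(self, flat_image):
        with pytest.raises(ValueError):
            HessianParams(size_range_um=(44.0, 15.0))
        with pytest.raises(ValueError):
            HessianParams(n_scales=1)


class TestGabor:
    def test_constant_image_gives_zero(self, flat_image):
        """Zero-mean kernels: constant input has exactly zero response."""
        assert gabor_enhance(flat_image).pixels.max() == 0.0

    def test_bar_argmax_orientation_is_along_bar(self):
        px = np.full((160, 160), 0.2)
        px[78:82, :] = 0.9  # horizontal bar
        img = EnFaceAngiogram(px, 15.0, 15.0)
        p = GaborParams(wavelength_px=16, sigma_px=6.0)
        arg = gabor_argmax_orientation(img, p)
        # carrier perpendicular to the bar = envelope along it: theta = pi/2
        assert (arg[79:81, 60:100] == 8).all()

    def test_half_turn_symmetry(self):
        """Response of the 180deg-rotated image is the rotated response."""
        rng = np.random.default_rng(3)
        px = np.clip(0.4 + 0.2 * rng.standard_normal((96, 128)), 0, 1)
        img = EnFaceAngiogram(px, 15.0, 15.0)
        rot = EnFaceAngiogram(px[::-1, ::-1].copy(), 15.0, 15.0)
        p = GaborParams(wavelength_px=12, sigma_px=5.0)
        a = gabor_enhance(img, p).pixels[::-1, ::-1]
        b = gabor_enhance(rot, p).pixels
        assert np.allclose(a, b, atol=1e-9)

    def test_aliasing_wavelength_rejected(self):
        with pytest.raises(ValueError, match="aliasing"):
            GaborParams(wavelength_px=1.5)

    def test_orientation_bank_spans_pi(self):
        with pytest.raises(ValueError):
            GaborParams(n_orientations=12, orientation_interval_rad=np.pi / 16)


class TestBayesianResidual:
    def test_zero_noise_is_exact_identity(self, bar_image):
        out = bayesian_residual_enhance(bar_image, BrtParams(noise_sd_estimate=0.0))
        np.testing.assert_array_equal(out.pixels, bar_image.pixels)

    def test_pure_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        px = np.clip(0.5 + 0.1 * rng.standard_normal((200, 200)), 0, 1)
        img = EnFaceAngiogram(px, 15.0, 15.0)
        out = bayesian_residual_enhance(img, BrtParams(noise_sd_estimate=0.1))
        assert out.pixels.var() < 0.5 * px.var()

    def test_bar_snr_not_degraded(self):
        rng = np.random.default_rng(2)
        base = np.full((120, 200), 0.2)
        base[59:61, :] = 0.8
        px = np.clip(base + 0.08 * rng.standard_normal(base.shape), 0, 1)
        img = EnFaceAngiogram(px, 15.0, 15.0)
        out = bayesian_residual_enhance(img)
        assert _snr(out.pixels) >= _snr(px)

    def test_invalid_levels(self):
        with pytest.raises(ValueError):
            BrtParams(n_levels=1)


@pytest.mark.parametrize("name", ["none", "hessian", "gabor", "bayesian"])
def test_filters_preserve_metadata_and_range(name):
    rng = np.random.default_rng(5)
    px = np.clip(0.4 + 0.2 * rng.standard_normal((100, 140)), 0, 1)
    img = EnFaceAngiogram(px, 18.75, 16.85, slab="SCP", subject_id="S1", visit=2)
    out = apply_filter(img, name)
    assert out.pitch_x_um == img.pitch_x_um and out.pitch_y_um == img.pitch_y_um
    assert out.slab == "SCP" and out.subject_id == "S1" and out.visit == 2
    assert np.isfinite(out.pixels).all()
    assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


@pytest.mark.parametrize("name", ["hessian", "gabor", "bayesian"])
def test_filters_deterministic(name):
    rng = np.random.default_rng(6)
    px = np.clip(0.4 + 0.2 * rng.standard_normal((80, 100)), 0, 1)
    img = EnFaceAngiogram(px, 18.75, 16.85)
    a = apply_filter(img, name).pixels
    b = apply_filter(img, name).pixels
    np.testing.assert_array_equal(a, b)


def test_shift_equivariance_on_interior():
    """Translating the input translates the response (away from borders)."""
    rng = np.random.default_rng(7)
    px = np.clip(0.3 + 0.2 * rng.standard_normal((140, 180)), 0, 1)
    px[70:73, 30:150] = 0.95
    img = EnFaceAngiogram(px, 15.0, 15.0)
    shifted = EnFaceAngiogram(np.roll(px, (0, 10), axis=(0, 1)), 15.0, 15.0)
    a = np.roll(hessian_vesselness(img).pixels, (0, 10), axis=(0, 1))
    b = hessian_vesselness(shifted).pixels
    interior = (slice(20, -20), slice(30, -30))
    assert np.allclose(a[interior], b[interior], atol=1e-6)
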