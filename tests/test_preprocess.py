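import numpy as np
import pytest

from hyperflux.io_core import BrightField, SpectralStack
from hyperflux.preprocess import (
    BadPixelMask,
    IlluminationField,
    denoise_poisson,
    detect_bad_pixels,
    estimate_background,
    estimate_background_field,
    estimate_illumination,
    flatten_illumination,
    preprocess_stack,
    repair_bad_pixels,
    subtract_background,
)
from hyperflux.synth import SceneParams, make_scene


class TestBadPixels:
    def test_dead_pixel_flagged(self, rng):
        data = rng.uniform(10, 20, (8, 8, 5))
        data[3, 4, :] = 0.0
        mask = detect_bad_pixels(SpectralStack(data=data), saturation_value=100.0)
        assert mask.mask[3, 4]
        assert mask.n_flagged == 1

    def test_saturated_pixel_needs_enough_channels(self, rng):
        data = rng.uniform(10, 20, (8, 8, 6))
        data[2, 2, :5] = 100.0  # 5 channels at saturation -> flagged
        data[5, 5, :2] = 100.0  # only 2 -> not flagged at default K=3
        mask = detect_bad_pixels(SpectralStack(data=data), saturation_value=100.0)
        assert mask.mask[2, 2]
        assert not mask.mask[5, 5]

    def test_empty_mask_repair_is_identity(self, rng):
        stack = SpectralStack(data=rng.uniform(1, 2, (6, 6, 4)))
        mask = detect_bad_pixels(stack, saturation_value=1e9)
        out = repair_bad_pixels(stack, mask)
        np.testing.assert_array_equal(out.data, stack.data)

    def test_dead_pixel_in_constant_image_repaired_to_constant(self):
        data = np.full((8, 8, 3), 7.0)
        data[4, 4, :] = 0.0
        stack = SpectralStack(data=data)
        mask = detect_bad_pixels(stack, saturation_value=100.0)
        out = repair_bad_pixels(stack, mask)
        np.testing.assert_allclose(out.data[4, 4], 7.0)

    def test_fully_flagged_image_rejected(self):
        stack = SpectralStack(data=np.zeros((4, 4, 2)))
        mask = detect_bad_pixels(stack, saturation_value=1.0)
        with pytest.raises(ValueError, match="fully-flagged"):
            repair_bad_pixels(stack, mask)

    def test_injected_bad_pixels_recovered_on_scene(self, default_scene):
        stack, _, truth = default_scene
        mask = detect_bad_pixels(stack, saturation_value=SceneParams().saturation_value)
        injected = truth.bad_pixels_true
        recall = (mask.mask & injected).sum() / injected.sum()
        precision = (mask.mask & injected).sum() / max(mask.mask.sum(), 1)
        assert recall == 1.0
        assert precision >= 0.99


class TestBackground:
    def test_constant_background_recovered(self, rng):
        b = rng.uniform(5, 10, 6)
        data = np.zeros((20, 20, 6)) + b
        data[5:10, 5:10, :] += 50.0  # some tissue
        est = estimate_background(SpectralStack(data=data))
        np.testing.assert_allclose(est, b, rtol=1e-9)

    def test_zero_background_estimates_near_zero(self, rng):
        data = np.zeros((20, 20, 4))
        data[2:6, 2:6, :] = rng.uniform(40, 60, (4, 4, 4))
        est = estimate_background(SpectralStack(data=data))
        np.testing.assert_allclose(est, 0.0, atol=1e-9)

    def test_subtract_then_reestimate_is_near_zero(self, rng):
        b = rng.uniform(5, 10, 4)
        data = np.zeros((20, 20, 4)) + b
        data[5:9, 5:9, :] += 30.0
        stack = SpectralStack(data=data)
        sub = subtract_background(stack, estimate_background(stack))
        second = estimate_background(sub)
        np.testing.assert_allclose(second, 0.0, atol=1e-9)

    def test_smooth_field_recovers_injected_background(self, endmembers69):
        p = SceneParams(size=96, snr_db=np.inf, bad_pixel_fraction=0.0, illumination_range=1e-12)
        stack, _, truth = make_scene(p, endmembers69, (0.3, 0.3, 0.3), seed=4)
        field = estimate_background_field(stack)
        err = np.linalg.norm(field - truth.background_true) / np.linalg.norm(
            truth.background_true
        )
        assert err < 0.25  # smooth interpolation under tissue cannot be exact


class TestIllumination:
    def test_flat_scene_gives_unit_field(self):
        stack = SpectralStack(data=np.full((32, 32, 4), 10.0))
        field = estimate_illumination(stack, method="polynomial")
        np.testing.assert_allclose(field.field, 1.0, atol=0.02)

    def test_linear_gradient_recovered_within_five_percent(self, rng):
        h = w = 64
        grad = np.linspace(0.5, 1.5, w)[None, :] * np.ones((h, 1))
        grad = grad / grad.mean()
        base = rng.uniform(80, 120, (h, w, 5))
        stack = SpectralStack(data=base * grad[..., None])
        est = estimate_illumination(stack, method="polynomial")
        rel_rmse = np.sqrt(np.mean(((est.field - grad) / grad) ** 2))
        assert rel_rmse <= 0.05

    def test_flatten_then_reestimate_is_unit(self, rng):
        h = w = 64
        grad = 1.0 + 0.4 * np.linspace(-1, 1, w)[None, :] * np.ones((h, 1))
        grad = grad / grad.mean()
        stack = SpectralStack(data=np.full((h, w, 3), 50.0) * grad[..., None])
        est = estimate_illumination(stack, method="polynomial")
        flat = flatten_illumination(stack, est)
        second = estimate_illumination(flat, method="polynomial")
        assert np.abs(second.field - 1.0).max() < 0.02

    def test_field_of_ones_is_identity(self, rng):
        stack = SpectralStack(data=rng.uniform(1, 2, (8, 8, 3)))
        out = flatten_illumination(stack, IlluminationField(field=np.ones((8, 8))))
        np.testing.assert_array_equal(out.data, stack.data)

    def test_flatten_twice_differs_from_once(self, rng):
        stack = SpectralStack(data=rng.uniform(1, 2, (16, 16, 3)))
        f = IlluminationField(field=1.0 + 0.2 * np.linspace(-1, 1, 16)[None, :] * np.ones((16, 1)))
        once = flatten_illumination(stack, f)
        twice = flatten_illumination(once, f)
        assert not np.allclose(once.data, twice.data)

    def test_non_positive_field_rejected(self):
        with pytest.raises(ValueError):
            IlluminationField(field=np.zeros((4, 4)))

    def test_brightfield_method_recovers_scene_field(self, default_scene):
        stack, bf, truth = default_scene
        est = estimate_illumination(stack, brightfield=bf)
        rel = np.sqrt(np.mean(((est.field - truth.illumination_true) / truth.illumination_true) ** 2))
        assert rel <= 0.05


class TestDenoise:
    def test_sqrt_transform_stabilises_variance(self, rng):
        """var(sqrt(X + 3/8)) ~ 1/4 for Poisson X at moderate mean."""
        draws = rng.poisson(10.0, size=200_000)
        assert np.var(np.sqrt(draws + 3.0 / 8.0)) == pytest.approx(0.25, abs=0.02)

    def test_noiseless_stack_nearly_unchanged(self):
        data = np.full((32, 32, 3), 100.0)
        out = denoise_poisson(SpectralStack(data=data), gain=1.0)
        np.testing.assert_allclose(out.data, data, rtol=1e-6)

    def test_denoising_reduces_mse_on_smooth_scene(self, rng):
        # smooth spatial signal + strong shot noise (SNR ~20 dB at the mean)
        from scipy import ndimage

        base = 50.0 + 50.0 * ndimage.gaussian_filter(rng.uniform(0, 1, (64, 64)), 8)
        clean = np.repeat(base[..., None], 4, axis=2)
        gain = float(base.mean()) / 100.0  # ~100 counts at the mean
        noisy = rng.poisson(clean / gain) * gain
        den = denoise_poisson(SpectralStack(data=noisy), gain=gain, sigma=1.0)
        assert np.mean((den.data - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_output_non_negative(self, rng):
        noisy = rng.poisson(2.0, size=(16, 16, 3)).astype(float)
        out = denoise_poisson(SpectralStack(data=noisy), gain=1.0)
        assert out.data.min() >= 0


class TestChain:
    def test_chain_preserves_shape_and_nonnegativity(self, default_scene, preprocessed_scene):
        stack, _, _ = default_scene
        clean, qc = preprocessed_scene
        assert clean.data.shape == stack.data.shape
        assert clean.data.min() >= 0
        assert qc["n_bad_pixels"] == int(default_scene[2].bad_pixels_true.sum())

    def test_chain_strictly_reduces_mse_to_clean_truth(self, default_scene, preprocessed_scene, endmembers69):
        stack, _, truth = default_scene
        clean, _ = preprocessed_scene
        ideal = SceneParams().intensity_scale * np.einsum(
            "kij,kc->ijc", truth.abundance_true, endmembers69.spectra
        )
        mse_raw = np.mean((stack.data - ideal) ** 2)
        mse_clean = np.mean((clean.data - ideal) ** 2)
        assert mse_clean < mse_raw
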