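import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from ceboost.boost import (
    BoostParams,
    IodineMap,
    ce_boost_pipeline,
    combine_boost,
    denoise_iodine,
    register_pre_to_enhanced,
    subtract_iodine,
)
from ceboost.errors import ConfigError, GeometryError
from ceboost.phantom import make_phantom
from ceboost.volume_io import CTVolume

from conftest import compact_spec


def _identity_params(**kw):
    return BoostParams(registration="none", denoiser="identity",
                       clamp_negative_iodine=False, **kw)


class TestSubtract:
    def test_identical_volumes_give_zero_map(self):
        vol = CTVolume(np.full((4, 4, 4), 40.0), (1, 1, 1))
        iodine = subtract_iodine(vol, vol)
        np.testing.assert_array_equal(iodine.data, 0.0)
        assert iodine.provenance == "raw"

    def test_vessel_iodine_matches_truth(self, clean_phantom):
        spec, pre, enhanced, truth = clean_phantom
        iodine = subtract_iodine(enhanced, pre, clamp_negative=False)
        np.testing.assert_allclose(iodine.data, truth.iodine.data, atol=1e-12)
        v = spec.vessels[0]
        idx = tuple(enhanced.mm_to_voxel((4.0, v.start[1], v.start[2])).round().astype(int))
        assert iodine.data[idx] == v.hu_enhanced - v.hu_pre

    def test_clamping_removes_negative_values(self, rng):
        enhanced = CTVolume(rng.normal(0, 5, (6, 6, 6)), (1, 1, 1))
        pre = CTVolume(rng.normal(0, 5, (6, 6, 6)), (1, 1, 1))
        assert subtract_iodine(enhanced, pre, clamp_negative=True).data.min() >= 0

    def test_shape_mismatch_rejected(self):
        a = CTVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        b = CTVolume(np.zeros((4, 4, 5)), (1, 1, 1))
        with pytest.raises(GeometryError):
            subtract_iodine(a, b)


class TestDenoise:
    @pytest.mark.parametrize("denoiser", ["identity", "gaussian", "bilateral", "nlm"])
    def test_constant_map_unchanged(self, denoiser):
        vol = CTVolume(np.full((8, 16, 16), 120.0), (0.5, 0.5, 0.5))
        params = BoostParams(denoiser=denoiser)
        out = denoise_iodine(IodineMap(vol), params)
        np.testing.assert_allclose(out.data, 120.0, atol=1e-6)
        assert out.provenance == "denoised"

    @pytest.mark.parametrize("denoiser", ["gaussian", "bilateral", "nlm"])
    def test_noise_sd_strictly_decreases(self, noisy_phantom, denoiser):
        spec, pre, enhanced, truth = noisy_phantom
        raw = subtract_iodine(enhanced, pre, clamp_negative=False)
        out = denoise_iodine(raw, BoostParams(denoiser=denoiser))
        core = binary_erosion(truth.masks["fat"], iterations=3)
        assert out.data[core].std(ddof=1) < raw.data[core].std(ddof=1)

    def test_gaussian_kernel_preserves_mass(self):
        data = np.zeros((17, 17, 17))
        data[8, 8, 8] = 1000.0
        vol = CTVolume(data, (0.5, 0.5, 0.5))
        out = denoise_iodine(IodineMap(vol), BoostParams(denoiser="gaussian"))
        assert abs(out.data.sum() - 1000.0) < 1e-3

    def test_unknown_denoiser_rejected(self):
        with pytest.raises(ConfigError, match="denoiser"):
            BoostParams(denoiser="wavelet").validate()

    def test_denoised_map_cannot_be_denoised_again(self):
        vol = CTVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        done = IodineMap(vol, provenance="denoised")
        with pytest.raises(ConfigError):
            denoise_iodine(done, BoostParams())


class TestCombine:
    def test_zero_weight_returns_enhanced(self, rng):
        enhanced = CTVolume(rng.normal(40, 10, (6, 6, 6)), (1, 1, 1))
        iodine = IodineMap(enhanced.with_data(rng.normal(0, 5, (6, 6, 6))),
                           provenance="denoised")
        out = combine_boost(enhanced, iodine, BoostParams(weight=0.0))
        np.testing.assert_array_equal(out.data, enhanced.data)

    def test_vessel_center_doubles_enhancement(self, clean_phantom):
        spec, pre, enhanced, truth = clean_phantom
        iodine = denoise_iodine(subtract_iodine(enhanced, pre), _identity_params())
        out = combine_boost(enhanced, iodine, _identity_params(weight=1.0))
        v = spec.vessels[0]
        idx = tuple(enhanced.mm_to_voxel((4.0, v.start[1], v.start[2])).round().astype(int))
        assert out.data[idx] == v.hu_enhanced + (v.hu_enhanced - v.hu_pre)  # 855 for defaults

    def test_unenhancing_voxels_untouched(self, clean_phantom):
        spec, pre, enhanced, truth = clean_phantom
        iodine = denoise_iodine(subtract_iodine(enhanced, pre), _identity_params())
        out = combine_boost(enhanced, iodine, _identity_params(weight=1.0))
        fat = truth.masks["fat"]
        np.testing.assert_array_equal(out.data[fat], enhanced.data[fat])

    def test_raw_iodine_rejected(self):
        vol = CTVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ConfigError):
            combine_boost(vol, IodineMap(vol, provenance="raw"), BoostParams())

    def test_monotone_in_weight(self, clean_phantom):
        spec, pre, enhanced, truth = clean_phantom
        vessel = truth.masks["vessels"]
        means = []
        for w in (0.0, 0.5, 1.0, 1.5):
            boosted, _, _ = ce_boost_pipeline(
                pre, enhanced, _identity_params(weight=w)
            )
            means.append(boosted.data[vessel].mean())
        assert np.all(np.diff(means) >= 0)


class TestRegistration:
    def test_mode_none_is_bitwise_identity(self, rng):
        pre = CTVolume(rng.normal(40, 10, (8, 8, 8)), (1, 1, 1))
        enhanced = CTVolume(rng.normal(40, 10, (8, 8, 8)), (1, 1, 1))
        aligned, t = register_pre_to_enhanced(pre, enhanced, mode="none")
        assert aligned is pre and t.is_identity

    def test_self_registration_stays_put(self, clean_phantom):
        spec, pre, enhanced, _ = clean_phantom
        _, t = register_pre_to_enhanced(enhanced, enhanced, mode="rigid")
        angle, shift = t.magnitude()
        assert shift <= 0.1 * min(spec.spacing)
        assert angle < 0.1

    def test_known_translation_recovered(self):
        from ceboost.transforms import RigidTransform

        truth_t = RigidTransform(translation_mm=(0.0, 0.0, 2.0), center_mm=(4, 18, 18))
        spec = compact_spec(noise_sigma_hu=0.0, misalignment=truth_t)
        pre, enhanced, truth = make_phantom(spec)
        _, recovered = register_pre_to_enhanced(pre, enhanced, mode="rigid")
        angle, shift = truth.transform.compose(recovered).magnitude()
        assert shift < 0.25
        assert angle < 0.25


class TestPipeline:
    def test_linearity_identity_denoiser(self, rng):
        """identity denoiser + w=1 collapses to boosted = 2*enhanced - pre,
        exactly, on integer-quantized HU volumes (as CT data is)."""
        enhanced = CTVolume(
            rng.integers(-1000, 2000, (16, 16, 16)).astype(float), (1, 1, 1)
        )
        pre = CTVolume(
            rng.integers(-1000, 2000, (16, 16, 16)).astype(float), (1, 1, 1)
        )
        boosted, iodine, _ = ce_boost_pipeline(pre, enhanced, _identity_params())
        np.testing.assert_array_equal(boosted.data, 2.0 * enhanced.data - pre.data)

    def test_geometry_preserved_end_to_end(self, noisy_phantom):
        spec, pre, enhanced, _ = noisy_phantom
        boosted, iodine, _ = ce_boost_pipeline(
            pre, enhanced, BoostParams(registration="none")
        )
        assert boosted.same_grid(enhanced)
        assert iodine.volume.same_grid(enhanced)

    def test_no_enhancement_means_no_boost(self, clean_phantom):
        spec, pre, enhanced, truth = clean_phantom
        boosted, _, _ = ce_boost_pipeline(
            enhanced, enhanced, BoostParams(registration="none")
        )
        # zero iodine everywhere: boosted deviates only by denoising
        # tolerance; stay beyond the denoiser's influence radius (patch
        # distance + patch half-width voxels) of any compartment edge
        core = binary_erosion(truth.masks["fat"], iterations=6)
        assert core.sum() > 100
        assert np.abs(boosted.data[core] - enhanced.data[core]).max() < 1.0

    def test_vessel_attenuation_and_noise_move_as_designed(self, noisy_phantom):
        spec, pre, enhanced, truth = noisy_phantom
        boosted, _, _ = ce_boost_pipeline(
            pre, enhanced, BoostParams(registration="none")
        )
        vessel = truth.masks["vessels"]
        assert boosted.data[vessel].mean() > enhanced.data[vessel].mean()
        core = binary_erosion(truth.masks["fat"], iterations=3)
        assert boosted.data[core].std(ddof=1) < enhanced.data[core].std(ddof=1)
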