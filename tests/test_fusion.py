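"""Activity maps, choose-max rule, reconstruction, end-to-end pipeline."""

import numpy as np
import pytest

from oracles import activity_loop, window_mean_loop
from sparsefuse import (
    CoefficientStack,
    CSCConfig,
    FusionConfig,
    ImagePair,
    PipelineConfig,
    activity_map,
    choose_max,
    enhance,
    fuse,
    mutual_information,
    reconstruct,
    smooth_activity,
)

# small helper: an impulse cartoon bank makes reconstruction transparent
def _impulse_bank():
    from test_csc import impulse_bank

    return impulse_bank()


def _stack(component, arrays):
    return CoefficientStack(component, np.stack(arrays)).validate()


class TestActivity:
    def test_single_map_is_absolute_value(self, rng):
        maps = rng.standard_normal((1, 8, 8))
        act = activity_map(CoefficientStack("c", maps))
        assert np.allclose(act.raw, np.abs(maps[0]))

    def test_l1_of_vector_per_pixel(self):
        maps = np.zeros((2, 8, 8))
        maps[0, 3, 4], maps[1, 3, 4] = 3.0, -4.0
        act = activity_map(CoefficientStack("c", maps))
        assert act.raw[3, 4] == 7.0

    def test_matches_loop_oracle(self, rng):
        maps = rng.standard_normal((4, 8, 8))
        act = activity_map(CoefficientStack("t", maps))
        assert np.allclose(act.raw, activity_loop(maps), atol=1e-12)


class TestSmoothing:
    def test_zero_half_width_is_identity(self, rng):
        act = activity_map(CoefficientStack("c", rng.random((2, 8, 8))))
        sm = smooth_activity(act, 0)
        assert np.array_equal(sm.smoothed, act.raw)

    def test_constant_map_unchanged(self):
        act = activity_map(CoefficientStack("c", np.full((1, 8, 8), 0.3)))
        assert np.allclose(smooth_activity(act, 2).smoothed, 0.3)

    def test_center_impulse_averages(self):
        raw = np.zeros((9, 9))
        raw[4, 4] = 9.0
        act = activity_map(CoefficientStack("c", raw[None]))
        assert smooth_activity(act, 1).smoothed[4, 4] == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        act = activity_map(CoefficientStack("c", rng.random((3, 10, 10))))
        sm = smooth_activity(act, 2)
        assert np.allclose(sm.smoothed, window_mean_loop(act.raw, 2), atol=1e-12)


def _acts(z0, z1):
    a0 = activity_map(CoefficientStack("c", np.zeros((1, *z0.shape))))
    a1 = activity_map(CoefficientStack("c", np.zeros((1, *z1.shape))))
    a0.smoothed, a1.smoothed = z0, z1
    return a0, a1


class TestChooseMax:
    def test_uniform_winner_copies_whole_stack(self, rng):
        s0 = CoefficientStack("c", rng.standard_normal((3, 8, 8)))
        s1 = CoefficientStack("c", rng.standard_normal((3, 8, 8)))
        fused = choose_max((s0, s1), _acts(np.ones((8, 8)), np.zeros((8, 8))))
        assert np.array_equal(fused.maps, s0.maps)

    def test_per_pixel_selector(self):
        z0 = np.kron(np.array([[1.0, 0.0], [0.0, 1.0]]), np.ones((4, 4)))
        z1 = 1.0 - z0
        s0 = CoefficientStack("c", np.zeros((1, 8, 8)))
        s1 = CoefficientStack("c", np.ones((1, 8, 8)))
        fused = choose_max((s0, s1), _acts(z0, z1))
        assert np.array_equal(fused.maps[0], z1)  # 1 where source 2 wins

    def test_tie_goes_to_configured_source(self, rng):
        s0 = CoefficientStack("c", rng.standard_normal((2, 8, 8)))
        s1 = CoefficientStack("c", rng.standard_normal((2, 8, 8)))
        same = np.ones((8, 8))
        fused0 = choose_max((s0, s1), _acts(same, same.copy()), FusionConfig(tie_break=0))
        fused1 = choose_max((s0, s1), _acts(same, same.copy()), FusionConfig(tie_break=1))
        assert np.array_equal(fused0.maps, s0.maps)
        assert np.array_equal(fused1.maps, s1.maps)

    def test_every_pixel_vector_is_verbatim_from_one_source(self, rng):
        s0 = CoefficientStack("c", rng.standard_normal((3, 8, 8)))
        s1 = CoefficientStack("c", rng.standard_normal((3, 8, 8)))
        fused = choose_max((s0, s1), _acts(rng.random((8, 8)), rng.random((8, 8))))
        from0 = np.all(fused.maps == s0.maps, axis=0)
        from1 = np.all(fused.maps == s1.maps, axis=0)
        assert np.all(from0 | from1)

    def test_shape_mismatch_rejected(self, rng):
        s0 = CoefficientStack("c", rng.standard_normal((3, 8, 8)))
        s1 = CoefficientStack("c", rng.standard_normal((2, 8, 8)))
        with pytest.raises(ValueError):
            choose_max((s0, s1), _acts(np.ones((8, 8)), np.ones((8, 8))))


class TestReconstruct:
    def test_zero_stacks_give_zero_image(self):
        bank = _impulse_bank()
        out = reconstruct(
            CoefficientStack("c", np.zeros((1, 16, 16))),
            CoefficientStack("t", np.zeros((1, 16, 16))),
            bank,
        )
        assert np.allclose(out, 0.0)

    def test_impulse_bank_sums_coefficient_maps(self, rng):
        bank = _impulse_bank()
        phi_c = rng.random((1, 16, 16)) * 0.5
        phi_t = np.zeros((1, 16, 16))
        out = reconstruct(CoefficientStack("c", phi_c), CoefficientStack("t", phi_t), bank)
        assert np.allclose(out, phi_c[0], atol=1e-12)

    def test_preclip_linearity(self, rng):
        from sparsefuse.csc import _bank_fft, fft_conv_sum

        bank = _impulse_bank()
        phi = rng.standard_normal((1, 16, 16)) * 0.1
        ff = _bank_fft(bank.cartoon, (16, 16))
        once = fft_conv_sum(phi, ff, (16, 16))
        twice = fft_conv_sum(2 * phi, ff, (16, 16))
        assert np.allclose(twice, 2 * once, atol=1e-12)


@pytest.fixture(scope="module")
def fast_cfg():
    cfg = PipelineConfig()
    cfg.csc = CSCConfig(max_inner=50, max_outer=5)
    return cfg


class TestPipeline:
    def test_output_shape_and_range(self, phantom_pair_64, fast_cfg):
        fused = fuse(phantom_pair_64, fast_cfg)
        assert fused.shape == phantom_pair_64.ct.shape
        assert fused.min() >= 0.0 and fused.max() <= 1.0

    def test_self_fusion_recovers_enhanced_image(self, phantom_pair_64, fast_cfg):
        img = phantom_pair_64.ct
        fused = fuse(ImagePair(img, img), fast_cfg)
        mae = float(np.abs(fused - enhance(img, fast_cfg.enhancement)).mean())
        assert mae <= 0.05

    def test_deterministic_reruns_bit_identical(self, phantom_pair_64, fast_cfg):
        f1 = fuse(phantom_pair_64, fast_cfg)
        f2 = fuse(phantom_pair_64, fast_cfg)
        assert np.array_equal(f1, f2)

    def test_source_swap_symmetry_where_strictly_ordered(self, phantom_pair_64, fast_cfg):
        """Swapping CT and MRI only changes pixels where activities tie."""
        f_ab = fuse(phantom_pair_64, fast_cfg)
        f_ba = fuse(ImagePair(phantom_pair_64.mri, phantom_pair_64.ct), fast_cfg)
        frac_diff = float(np.mean(np.abs(f_ab - f_ba) > 1e-9))
        assert frac_diff <= 0.05

    def test_fused_image_shares_information_with_sources(self, phantom_pair_64, fast_cfg):
        fused = fuse(phantom_pair_64, fast_cfg)
        assert mutual_information(phantom_pair_64.ct, phantom_pair_64.mri, fused) > 0.0
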