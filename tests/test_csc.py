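"""Dictionary construction and the convolutional sparse coding solver."""

import numpy as np
import pytest

from oracles import circular_conv_loop
from sparsefuse import (
    CoefficientStack,
    CSCConfig,
    FilterBank,
    PhantomSpec,
    build_dictionary,
    csc_solve,
    decompose,
    expand_by_residual_similarity,
    make_pair,
    soft_threshold,
)
from sparsefuse.csc import _bank_fft, edge_taper, fft_conv_sum


def impulse_bank(s: int = 4) -> FilterBank:
    """Cartoon bank = the unit impulse; one zero-mean texture filter."""
    imp = np.zeros((1, s, s))
    imp[0, 0, 0] = 1.0
    tex = np.zeros((1, s, s))
    tex[0, 0, 0], tex[0, 0, 1] = 1.0, -1.0
    tex /= np.sqrt(2.0)
    return FilterBank(cartoon=imp, texture=tex).validate()


class TestDictionary:
    def test_default_bank_counts_and_unit_norms(self):
        bank = build_dictionary(CSCConfig())
        assert bank.cartoon.shape[0] == 8 and bank.texture.shape[0] == 16
        for f in (bank.cartoon, bank.texture):
            assert np.allclose(np.sqrt((f**2).sum(axis=(1, 2))), 1.0, atol=1e-12)

    def test_texture_atoms_zero_mean(self):
        bank = build_dictionary(CSCConfig())
        assert np.allclose(bank.texture.sum(axis=(1, 2)), 0.0, atol=1e-12)

    def test_cartoon_bank_contains_dc_atom(self):
        bank = build_dictionary(CSCConfig(kernel_size=8))
        assert np.allclose(bank.cartoon[0], 1.0 / 8.0, atol=1e-12)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            build_dictionary(CSCConfig(kernel_size=4, n_cartoon=10, n_texture=10))

    def test_save_load_round_trip(self, tmp_path):
        bank = build_dictionary(CSCConfig(n_cartoon=4, n_texture=6))
        bank.save(tmp_path / "bank.bin")
        back = FilterBank.load(tmp_path / "bank.bin")
        assert np.array_equal(back.cartoon, bank.cartoon)
        assert np.array_equal(back.texture, bank.texture)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x,t,expected", [(0.5, 1.0, 0.0), (2.0, 1.0, 1.0), (-2.0, 1.0, -1.0)]
    )
    def test_scalar_cases(self, x, t, expected):
        assert soft_threshold(np.array([x]), t)[0] == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.zeros(3), -0.1)


class TestFrequencyConvolution:
    def test_matches_circular_loop_oracle(self, rng):
        img = rng.random((16, 16))
        bank = build_dictionary(CSCConfig(n_cartoon=2, n_texture=3))
        ff = _bank_fft(bank.cartoon, img.shape)
        maps = rng.standard_normal((2, 16, 16))
        got = fft_conv_sum(maps, ff, img.shape)
        expected = sum(circular_conv_loop(maps[u], bank.cartoon[u]) for u in range(2))
        assert np.allclose(got, expected, atol=1e-10)


class TestSolver:
    def test_identity_dictionary_exact_recovery(self, rng):
        """With an impulse atom and no sparsity penalty the cartoon map
        must reproduce the image itself."""
        img = rng.random((16, 16))
        cfg = CSCConfig(nu_cartoon=0.0, nu_texture=0.0, max_inner=200, max_outer=3,
                        tol=1e-12, taper=0, kernel_size=4, n_cartoon=1, n_texture=1)
        sc, st, _ = csc_solve(img, impulse_bank(), cfg)
        recon = sc.maps[0]
        assert np.allclose(recon, img, atol=1e-10)

    def test_zero_image_gives_zero_stacks(self, fast_csc):
        sc, st, trace = csc_solve(np.zeros((16, 16)), cfg=fast_csc)
        assert np.all(sc.maps == 0) and np.all(st.maps == 0)
        assert trace[-1] == 0.0

    def test_objective_nonincreasing_and_beats_zero_solution(self, rng, fast_csc):
        img = rng.random((32, 32))
        _, _, trace = csc_solve(img, cfg=fast_csc)
        for a, b in zip(trace, trace[1:]):
            assert b <= a + 1e-6 * max(1.0, a)
        assert trace[-1] <= 0.5 * (img**2).sum()

    def test_near_exact_reconstruction_with_tiny_penalty(self):
        """With vanishing l1 weights and the impulse atom present the
        cartoon+texture reconstruction is essentially lossless (>=40 dB)."""
        img = make_pair(PhantomSpec(size=64, seed=3)).ct
        cfg = CSCConfig(nu_cartoon=1e-8, nu_texture=1e-8, max_inner=200,
                        max_outer=3, tol=1e-12, taper=0, kernel_size=4,
                        n_cartoon=1, n_texture=1)
        sc, st, _ = csc_solve(img, impulse_bank(), cfg)
        bank = impulse_bank()
        recon = fft_conv_sum(sc.maps, _bank_fft(bank.cartoon, img.shape), img.shape)
        recon += fft_conv_sum(st.maps, _bank_fft(bank.texture, img.shape), img.shape)
        mse = float(((recon - img) ** 2).mean())
        psnr = 10 * np.log10(1.0 / max(mse, 1e-300))
        assert psnr >= 40.0


class TestExpansion:
    def test_threshold_one_returns_stacks_unchanged(self, rng, fast_csc):
        img = rng.random((32, 32))
        stacks = csc_solve(img, cfg=fast_csc)[:2]
        cfg = CSCConfig(**{**fast_csc.__dict__, "tau": 1.0})
        out = expand_by_residual_similarity(img, stacks, cfg=cfg)
        assert out[0] is stacks[0] and out[1] is stacks[1]

    def test_zero_residual_returns_stacks_unchanged(self, rng):
        img = rng.random((16, 16))
        cfg = CSCConfig(nu_cartoon=0.0, nu_texture=0.0, max_inner=300, max_outer=3,
                        tol=1e-13, taper=0, kernel_size=4, n_cartoon=1, n_texture=1,
                        tau=0.0)
        stacks = csc_solve(img, impulse_bank(), cfg)[:2]
        out = expand_by_residual_similarity(img, stacks, impulse_bank(), cfg)
        assert np.allclose(out[0].maps, stacks[0].maps, atol=1e-8)

    def test_expansion_never_increases_reconstruction_error(self, fast_csc):
        img = make_pair(PhantomSpec(size=64, seed=5)).mri
        bank = build_dictionary(fast_csc)
        stacks = csc_solve(img, bank, fast_csc)[:2]
        cfg = CSCConfig(**{**fast_csc.__dict__, "tau": 0.5})

        def err(pair):
            ff_c = _bank_fft(bank.cartoon, img.shape)
            ff_t = _bank_fft(bank.texture, img.shape)
            recon = fft_conv_sum(pair[0].maps, ff_c, img.shape)
            recon += fft_conv_sum(pair[1].maps, ff_t, img.shape)
            return float(((img - recon) ** 2).sum())

        out = expand_by_residual_similarity(img, stacks, bank, cfg)
        assert err(out) <= err(stacks) + 1e-12


class TestDecompose:
    def test_piecewise_constant_energy_lands_in_cartoon(self):
        img = np.full((64, 64), 0.2)
        img[16:48, 16:48] = 0.8
        cartoon, texture = decompose(img, cfg=CSCConfig(max_inner=50, max_outer=5))
        e_c, e_t = (cartoon**2).sum(), (texture**2).sum()
        assert e_c / (e_c + e_t) >= 0.9

    def test_high_frequency_sinusoid_lands_in_texture(self):
        x = np.arange(64)
        X, Y = np.meshgrid(x, x)
        img = np.clip(0.5 + 0.45 * np.sin(2 * np.pi * X / 3) * np.sin(2 * np.pi * Y / 3), 0, 1)
        cfg = CSCConfig(max_inner=50, max_outer=5, taper=0)
        cartoon, texture = decompose(img, cfg=cfg)
        # compare detail energy after removing the mean offset the DC atom carries
        assert (texture**2).sum() > ((cartoon - cartoon.mean()) ** 2).sum()

    def test_zero_image_decomposes_to_zero(self, fast_csc):
        cartoon, texture = decompose(np.zeros((16, 16)), cfg=fast_csc)
        assert np.allclose(cartoon, 0) and np.allclose(texture, 0)


def test_edge_taper_zero_width_is_identity(rng):
    img = rng.random((16, 16))
    assert np.array_equal(edge_taper(img, 0), img)


def test_coefficient_stack_validation():
    with pytest.raises(ValueError):
        CoefficientStack("x", np.zeros((2, 8, 8))).validate()
    with pytest.raises(ValueError):
        CoefficientStack("c", np.full((1, 8, 8), np.nan)).validate()
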