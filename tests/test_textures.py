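import numpy as np
import pytest

from oracles import (
    naive_collage_maps,
    naive_dominant_orientations,
    naive_haralick_maps,
)
from periradiomics import textures as tx


@pytest.fixture()
def random_slice(rng):
    return rng.normal(size=(16, 16)) * 50 + 400


# ---------------------------------------------------------------------------
# Laws
# ---------------------------------------------------------------------------

class TestLaws:
    def test_kernel_sums(self):
        assert tx.LAWS_KERNELS_1D["L5"].sum() == 16
        for k in ("E5", "S5", "W5", "R5"):
            assert tx.LAWS_KERNELS_1D[k].sum() == 0

    def test_constant_image_responses(self):
        maps = tx.laws_maps(np.ones((12, 12)))
        assert len(maps) == 25
        assert np.allclose(maps["level-level"], 256.0)  # 16^2
        zero_sum = [n for n in maps if n != "level-level"]
        assert len(zero_sum) == 24
        for n in zero_sum:
            assert np.allclose(maps[n], 0.0)

    def test_matches_direct_convolution_oracle(self, random_slice):
        from scipy.ndimage import convolve

        maps = tx.laws_maps(random_slice)
        kern = np.outer(tx.LAWS_KERNELS_1D["S5"], tx.LAWS_KERNELS_1D["R5"])
        ref = convolve(random_slice, kern, mode="mirror")
        assert np.allclose(maps["spot-ripple"], ref)

    def test_too_small_slice_rejected(self):
        with pytest.raises(ValueError):
            tx.laws_maps(np.ones((4, 8)))


# ---------------------------------------------------------------------------
# Gabor
# ---------------------------------------------------------------------------

class TestGabor:
    def test_bank_size_and_order(self):
        names = tx.gabor_names()
        assert len(names) == 48
        assert names[0] == "f=0, theta=0"
        assert names[-1] == "f=32, theta=157.5"

    def test_printed_orientation_grid_available(self):
        names = tx.gabor_names(tx.GABOR_THETAS_PRINTED)
        assert "f=2, theta=167.5" in names

    def test_constant_image_zero_response_for_nonzero_frequency(self):
        maps = tx.gabor_maps(np.full((20, 20), 700.0))
        for f in (2, 4, 8, 16, 32):
            assert np.abs(maps[f"f={f}, theta=45"]).max() < 1e-8 * 700.0

    def test_rotation_equivariance_90_degrees(self, random_slice):
        """Response to a 90deg-rotated image at theta equals the rotated
        response at theta+90 (interior pixels)."""
        maps = tx.gabor_maps(random_slice)
        maps_rot = tx.gabor_maps(np.rot90(random_slice))
        for f in (8, 16):
            a = np.rot90(maps[f"f={f}, theta=112.5"])  # theta + 90 = 112.5
            b = maps_rot[f"f={f}, theta=22.5"]
            interior = (slice(4, -4), slice(4, -4))
            assert np.allclose(a[interior], b[interior], atol=1e-6 * np.abs(a).max())

    def test_intensity_shift_invariance(self, random_slice):
        base = tx.gabor_maps(random_slice)
        shifted = tx.gabor_maps(random_slice + 123.0)
        for f in (2, 32):
            name = f"f={f}, theta=0"
            scale = np.abs(base[name]).max()
            assert np.allclose(base[name], shifted[name], atol=1e-6 * max(scale, 1.0))


# ---------------------------------------------------------------------------
# Haralick
# ---------------------------------------------------------------------------

class TestHaralick:
    def test_constant_window_entropy_zero_energy_one(self):
        maps = tx.haralick_maps(np.ones((10, 10)))
        assert len(maps) == 13
        assert np.allclose(maps["entropy"], 0.0)
        assert np.allclose(maps["energy"], 1.0)

    def test_checkerboard_contrast_one_horizontal_offsets(self):
        """2-level checkerboard, 0-degree offsets: every horizontal pair
        differs by one level, so inertia (contrast) is exactly 1."""
        board = np.indices((9, 9)).sum(axis=0) % 2
        spec = tx.HaralickSpec(n_gray_levels=2, directions=((0, 1),))
        maps = tx.haralick_maps(board.astype(float), spec)
        assert np.allclose(maps["inertia"], 1.0)

    def test_windowed_maps_match_naive_double_loop(self, rng):
        img = rng.normal(size=(16, 16))
        spec = tx.HaralickSpec(n_gray_levels=8)
        got = tx.haralick_maps(img, spec)
        ref = naive_haralick_maps(img, 5, 8, tx.COOC_DIRECTIONS)
        for s in tx.HARALICK_STATISTICS:
            assert np.allclose(got[s], ref[s], atol=1e-10), s

    def test_quantization_level_validation(self):
        with pytest.raises(ValueError):
            tx.HaralickSpec(n_gray_levels=1)

    def test_masked_evaluation_leaves_nan_outside(self, rng):
        img = rng.normal(size=(10, 10))
        mask = np.zeros((10, 10), bool)
        mask[4:6, 4:6] = True
        maps = tx.haralick_maps(img, mask=mask)
        assert np.isfinite(maps["entropy"][mask]).all()
        assert np.isnan(maps["entropy"][~mask]).all()


# ---------------------------------------------------------------------------
# CoLlAGe
# ---------------------------------------------------------------------------

class TestCollage:
    def test_planar_ramp_entropy_zero(self):
        ramp = np.tile(np.arange(16.0), (16, 1))
        maps = tx.collage_maps(ramp)
        assert len(maps) == 13
        assert np.allclose(maps["entropy"], 0.0)

    def test_orientations_match_per_pixel_svd(self, rng):
        img = rng.normal(size=(12, 12))
        fast = tx.dominant_gradient_orientations(img)
        slow = naive_dominant_orientations(img, 5)
        diff = np.abs(fast - slow)
        diff = np.minimum(diff, np.pi - diff)  # orientation wrap-around
        assert diff.max() < 1e-8

    def test_windowed_maps_match_naive_double_loop(self, rng):
        img = rng.normal(size=(16, 16))
        spec = tx.CollageSpec(n_orientation_bins=16)
        got = tx.collage_maps(img, spec)
        ref = naive_collage_maps(img, 5, 16, tx.COOC_DIRECTIONS)
        for s in tx.HARALICK_STATISTICS:
            assert np.allclose(got[s], ref[s], atol=1e-10), s

    def test_disordered_field_has_higher_entropy_than_ramp(self):
        from periradiomics import synthetic

        cfg = synthetic.PhantomConfig(
            seed=5,
            texture_effect=synthetic.TextureEffect(
                gradient_disorder=1.0, enhancement_heterogeneity=0.8
            ),
            kinetics=(0.4, 0.8),
            noise_sd=0.0,
        )
        series, tumor = synthetic.generate_phantom(cfg)
        z = tumor.sum(axis=(1, 2)).argmax()
        disordered = tx.collage_maps(series.data[1][z], mask=tumor[z])
        ramp = tx.collage_maps(np.tile(np.arange(48.0), (48, 1)))
        assert np.nanmean(disordered["entropy"]) > np.nanmean(ramp["entropy"])


# ---------------------------------------------------------------------------
# Bank-level invariants
# ---------------------------------------------------------------------------

class TestBank:
    def test_99_descriptors_with_family_decomposition(self, random_slice):
        bank = tx.texture_bank(random_slice)
        assert len(bank) == 99
        counts = {}
        for fam in bank.families.values():
            counts[fam] = counts.get(fam, 0) + 1
        assert counts == {"Laws": 25, "Gabor": 48, "Haralick": 13, "CoLlAGe": 13}

    def test_descriptor_names_disjoint_across_families(self):
        names = tx.descriptor_names()
        assert len(names) == len(set(names)) == 99

    def test_translation_equivariance_interior(self, rng):
        """Integer image shifts shift all filter maps (interior pixels)."""
        img = rng.normal(size=(24, 24))
        shifted = np.roll(img, (2, 3), axis=(0, 1))
        interior = (slice(8, -8), slice(8, -8))
        for compute in (
            lambda x: tx.laws_maps(x)["edge-spot"],
            lambda x: tx.gabor_maps(x)["f=32, theta=45"],  # compact kernel: no edge contamination
            lambda x: tx.haralick_maps(x, tx.HaralickSpec(n_gray_levels=8))["entropy"],
            lambda x: tx.collage_maps(x, tx.CollageSpec(n_orientation_bins=16))["entropy"],
        ):
            a = np.roll(compute(img), (2, 3), axis=(0, 1))
            b = compute(shifted)
            scale = max(np.abs(a[interior]).max(), 1.0)
            assert np.allclose(a[interior], b[interior], atol=1e-9 * scale)

    def test_intensity_shift_invariance_of_gradient_and_zero_sum_maps(self, rng):
        img = rng.normal(size=(16, 16))
        a = tx.collage_maps(img)["entropy"]
        b = tx.collage_maps(img + 55.5)["entropy"]
        assert np.allclose(a, b, atol=1e-6)
        la = tx.laws_maps(img)["ripple-ripple"]
        lb = tx.laws_maps(img + 55.5)["ripple-ripple"]
        assert np.allclose(la, lb, atol=1e-6 * max(np.abs(la).max(), 1.0))

    def test_per_pixel_glcm_is_normalized(self, rng):
        """Every per-pixel GLCM sums to 1 before statistics: a constant map
        plus the naive-window oracle pins the normalization."""
        from oracles import naive_quantize, naive_window_glcm

        img = rng.normal(size=(8, 8))
        levels = naive_quantize(img, 8)
        P = naive_window_glcm(levels, (4, 4), 5, 8, tx.COOC_DIRECTIONS)
        assert P.sum() == pytest.approx(1.0)
        assert np.allclose(P, P.T)
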