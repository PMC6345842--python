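"""Perturbation operators: identity no-ops, analytic oracles, determinism,
and chain expansion combinatorics."""

import numpy as np
import pytest

from radperturb import (
    ParameterError,
    PerturbationChain,
    PhantomSpec,
    RoiMask,
    SupervoxelSettings,
    VolumetricImage,
    adapt_volume,
    add_noise,
    contour_randomise,
    default_chain_registry,
    estimate_noise_sd,
    expand_chain,
    generate_phantom,
    permute_translations,
    rotate,
    translate,
)
from radperturb.perturb import slic_supervoxels
from radperturb.processing import ProcessingConfig


class TestRotation:
    def test_zero_angle_is_identity(self, textured_phantom):
        img, mask = textured_phantom
        out_img, out_mask = rotate(img, mask, 0.0)
        np.testing.assert_array_equal(out_img.voxels, img.voxels)
        np.testing.assert_array_equal(out_mask.values, mask.labels.astype(float))

    def test_quarter_turn_matches_index_permutation(self, rng):
        # Odd in-plane size so the grid centre is a voxel centre: trilinear
        # sampling then lands on exact input voxels.
        vox = rng.normal(0, 50, (11, 11, 4))
        img = VolumetricImage(vox, (1, 1, 1))
        mask = RoiMask(np.ones(vox.shape, bool), (1, 1, 1))
        out, _ = rotate(img, mask, 90.0, centre="image_center")
        # CCW rotation by 90 deg about the centre: (x, y) -> (-y, x), i.e. the
        # output at (i, j) samples the input at (j, n-1-i).
        n = 11
        oracle = np.empty_like(vox)
        for i in range(n):
            for j in range(n):
                oracle[i, j, :] = vox[j, n - 1 - i, :]
        np.testing.assert_allclose(out.voxels, oracle, atol=1e-9)

    def test_rotation_preserves_mean_on_uniform_sphere(self, sphere_phantom):
        # Trilinear interpolation of a constant region is exactly constant on
        # voxels whose whole interpolation stencil lies inside the ROI, so the
        # mean over the eroded rotated ROI must match the original intensity.
        from scipy import ndimage

        img, mask = sphere_phantom
        out_img, out_mask = rotate(img, mask, 13.0)
        interior = ndimage.binary_erosion(out_mask.values >= 0.999, iterations=1)
        before = img.voxels[mask.labels].mean()
        after = out_img.voxels[interior].mean()
        assert abs(after - before) < 0.5

    def test_non_finite_angle_rejected(self, sphere_phantom):
        img, mask = sphere_phantom
        with pytest.raises(ParameterError):
            rotate(img, mask, float("nan"))


class TestTranslation:
    def test_zero_shift_is_identity(self, textured_phantom):
        img, mask = textured_phantom
        out_img, out_mask = translate(img, mask, (0, 0, 0))
        np.testing.assert_array_equal(out_img.voxels, img.voxels)
        np.testing.assert_array_equal(out_mask.values, mask.labels.astype(float))

    def test_half_voxel_shift_on_ramp_gives_neighbour_midpoints(self):
        ramp = np.broadcast_to(
            np.arange(16, dtype=float)[:, None, None], (16, 8, 8)
        ).copy()
        img = VolumetricImage(ramp, (1, 1, 1))
        mask = RoiMask(np.ones(ramp.shape, bool), (1, 1, 1))
        out, _ = translate(img, mask, (0.5, 0, 0))
        interior = out.voxels[1:, :, :]
        expected = (ramp[1:, :, :] + ramp[:-1, :, :]) / 2.0
        np.testing.assert_allclose(interior, expected, atol=1e-12)

    def test_fraction_out_of_range_rejected(self, sphere_phantom):
        img, mask = sphere_phantom
        with pytest.raises(ParameterError):
            translate(img, mask, (1.0, 0, 0))

    @pytest.mark.parametrize(
        "fractions,expected", [([0.25, 0.5], 8), ([0.0], 1), ([0.25, 0.5, 0.75], 27)]
    )
    def test_permutation_counts(self, fractions, expected):
        assert len(permute_translations(fractions)) == expected

    def test_permutations_are_distinct_tuples(self):
        perms = permute_translations([0.2, 0.6])
        assert len(set(perms)) == 8
        assert all(len(p) == 3 for p in perms)


class TestNoise:
    def test_zero_sd_is_identity(self, textured_phantom):
        img, _ = textured_phantom
        np.testing.assert_array_equal(add_noise(img, 0.0, 1).voxels, img.voxels)

    def test_moments_of_added_noise(self):
        img = VolumetricImage(np.zeros((64, 64, 64)), (1, 1, 1))
        out = add_noise(img, 15.0, seed=7)
        diff = out.voxels - img.voxels
        assert abs(diff.mean()) < 0.5
        assert 14.5 <= diff.std() <= 15.5

    def test_same_seed_is_deterministic(self, textured_phantom):
        img, _ = textured_phantom
        a = add_noise(img, 10.0, seed=42)
        b = add_noise(img, 10.0, seed=42)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_negative_sd_rejected(self, textured_phantom):
        img, _ = textured_phantom
        with pytest.raises(ParameterError):
            add_noise(img, -1.0, 0)


class TestNoiseEstimation:
    def test_recovers_known_sigma_on_constant_background(self):
        rng = np.random.default_rng(0)
        img = VolumetricImage(40.0 + rng.normal(0, 20, (48, 48, 48)), (1, 1, 1))
        assert 17.0 <= estimate_noise_sd(img) <= 23.0

    def test_constant_image_estimates_zero(self):
        img = VolumetricImage(np.full((16, 16, 16), 25.0), (1, 1, 1))
        with pytest.warns(UserWarning):
            assert estimate_noise_sd(img) == 0.0

    def test_robust_to_linear_structure(self):
        # A steep ramp has naive SD ~ 74 HU but carries no noise.
        ramp = np.broadcast_to(
            np.linspace(-128, 128, 32)[:, None, None], (32, 32, 32)
        ).copy()
        img = VolumetricImage(ramp, (1, 1, 1))
        assert img.voxels.std() > 50.0
        assert estimate_noise_sd(img) < 2.0


class TestVolumeAdaptation:
    def test_tau_zero_is_identity(self, sphere_phantom):
        _, mask = sphere_phantom
        np.testing.assert_array_equal(adapt_volume(mask, 0.0).labels, mask.labels)

    @pytest.mark.parametrize("tau", [0.28, -0.28, 0.1, -0.1])
    def test_hits_target_volume_within_two_percent(self, sphere_phantom, tau):
        _, mask = sphere_phantom
        out = adapt_volume(mask, tau)
        target = (1.0 + tau) * mask.voxel_count
        assert abs(out.voxel_count - target) / target <= 0.02
        if tau > 0:
            assert np.all(out.labels[mask.labels])  # superset
        else:
            assert np.all(mask.labels[out.labels])  # subset

    def test_full_shrink_rejected(self, sphere_phantom):
        _, mask = sphere_phantom
        with pytest.raises(ParameterError):
            adapt_volume(mask, -1.0)


class TestContourRandomisation:
    def test_supervoxels_partition_the_region(self, textured_phantom):
        img, mask = textured_phantom
        labels, crop = slic_supervoxels(img, mask, SupervoxelSettings())
        assert labels.min() >= 1  # every voxel belongs to exactly one supervoxel
        assert labels.shape == img.voxels[crop].shape

    def test_same_seed_is_deterministic(self, textured_phantom):
        img, mask = textured_phantom
        a = contour_randomise(img, mask, seed=5)
        b = contour_randomise(img, mask, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_perturbs_but_preserves_gross_shape(self):
        spec = PhantomSpec(
            shape=(40, 40, 40), spacing=(1, 1, 1), radii=(10, 10, 10),
            texture="constant", noise_sd=10.0, seed=3,
        )
        img, mask = generate_phantom(spec)
        dices = []
        for seed in range(30):
            out = contour_randomise(img, mask, seed=seed)
            inter = (out.labels & mask.labels).sum()
            dices.append(2 * inter / (out.labels.sum() + mask.labels.sum()))
        dices = np.asarray(dices)
        assert np.median(dices) >= 0.80
        assert np.all(dices < 1.0)

    def test_oversized_supervoxels_rejected(self, sphere_phantom):
        from radperturb.errors import ConfigurationError

        img, mask = sphere_phantom
        with pytest.raises(ConfigurationError):
            contour_randomise(img, mask, 0, SupervoxelSettings(target_voxels=10**6))


class TestChains:
    def test_default_registry_has_18_chains_with_reference_counts(self):
        registry = default_chain_registry()
        assert len(registry) == 18
        expected = {
            "R": 27, "N": 30, "T": 27, "V": 29, "C": 30, "RT": 32, "RNT": 32,
            "RV": 30, "RC": 27, "TV": 40, "TC": 27, "RTC": 32, "RNTC": 32,
            "VC": 30, "RVC": 30, "RNVC": 30, "TVC": 40, "NTVC": 40,
        }
        for label, count in expected.items():
            assert PerturbationChain.from_label(label).size == count, label

    def test_operators_apply_in_fixed_order_regardless_of_label(self):
        chain = PerturbationChain.from_label(
            "CVR", {"rotation": [5.0], "volume": [0.1], "contour_repetitions": 1}
        )
        assert [s.kind for s in chain.specs] == [
            "rotation", "volume_adaptation", "contour_randomisation"
        ]

    def test_expansion_size_is_product_of_grids(self):
        chain = PerturbationChain.from_label(
            "RV", {"rotation": [-5, 0, 5], "volume": [-0.1, 0, 0.05, 0.1, 0.2]}
        )
        assert chain.size == 15

    def test_noise_chain_produces_requested_repetitions(self, textured_phantom):
        img, mask = textured_phantom
        chain = PerturbationChain.from_label("N", {"noise_repetitions": 5})
        samples = expand_chain(chain, img, mask, base_seed=1)
        assert len(samples) == 5
        # distinct noise realisations
        assert len({s.image.voxels.tobytes() for s in samples}) == 5

    def test_translation_chain_with_two_fractions_gives_eight_samples(self, textured_phantom):
        img, mask = textured_phantom
        chain = PerturbationChain.from_label("T", {"translation": [0.25, 0.5]})
        samples = expand_chain(chain, img, mask, base_seed=1)
        assert len(samples) == 8

    def test_samples_replay_bit_exactly(self, textured_phantom):
        img, mask = textured_phantom
        chain = PerturbationChain.from_label(
            "RVC", {"rotation": [8.0], "volume": [0.15], "contour_repetitions": 2}
        )
        cfg = ProcessingConfig(spacings=(2.0,))
        a = expand_chain(chain, img, mask, cfg, target_spacing=2.0, base_seed=3)
        b = expand_chain(chain, img, mask, cfg, target_spacing=2.0, base_seed=3)
        for sa, sb in zip(a, b):
            assert sa.params == sb.params and sa.seed == sb.seed
            np.testing.assert_array_equal(sa.image.voxels, sb.image.voxels)
            np.testing.assert_array_equal(sa.mask.labels, sb.mask.labels)

    def test_noise_only_distorts_image_and_v_c_only_the_mask(self, textured_phantom):
        img, mask = textured_phantom
        n = expand_chain(PerturbationChain.from_label("N", {"noise_repetitions": 1}),
                         img, mask, base_seed=0)[0]
        np.testing.assert_array_equal(n.mask.labels, mask.labels)
        assert not np.array_equal(n.image.voxels, img.voxels)
        v = expand_chain(PerturbationChain.from_label("V", {"volume": [0.2]}),
                         img, mask, base_seed=0)[0]
        np.testing.assert_array_equal(v.image.voxels, img.voxels)
        assert not np.array_equal(v.mask.labels, mask.labels)
        c = expand_chain(PerturbationChain.from_label("C", {"contour_repetitions": 1}),
                         img, mask, base_seed=0)[0]
        np.testing.assert_array_equal(c.image.voxels, img.voxels)
        assert not np.array_equal(c.mask.labels, mask.labels)
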