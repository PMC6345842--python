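"""Feature manifest combinatorics, analytic limits on phantoms, and
brute-force enumeration oracles for every texture-matrix builder."""

import itertools

import numpy as np
import pytest

from radperturb import ProcessingConfig, RoiMask, VolumetricImage
from radperturb.features import FAMILY_FEATURES, build_manifest, compute_features
from radperturb.features.texture import (
    DIRECTIONS_13,
    glcm_matrix,
    run_length_matrix,
    glszm_features,
    gldzm_features,
    ngtdm_features,
    ngldm_features,
)
from radperturb.processing import resegment


# ---------------------------------------------------------------------------
# Brute-force oracles (independent, loop-based implementations)
# ---------------------------------------------------------------------------

def oracle_glcm(levels, ng, d):
    m = np.zeros((ng, ng))
    nx, ny, nz = levels.shape
    for i, j, k in itertools.product(range(nx), range(ny), range(nz)):
        a = levels[i, j, k]
        x, y, z = i + d[0], j + d[1], k + d[2]
        if a > 0 and 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
            b = levels[x, y, z]
            if b > 0:
                m[a - 1, b - 1] += 1
                m[b - 1, a - 1] += 1
    return m


def oracle_runs(levels, ng, d):
    """Walk every line in direction d, recording maximal equal-level runs."""
    nx, ny, nz = levels.shape
    entries = []
    for i, j, k in itertools.product(range(nx), range(ny), range(nz)):
        # start of line: predecessor out of bounds
        pi, pj, pk = i - d[0], j - d[1], k - d[2]
        if 0 <= pi < nx and 0 <= pj < ny and 0 <= pk < nz:
            continue
        run_val, run_len = 0, 0
        x, y, z = i, j, k
        while 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
            v = levels[x, y, z]
            if v == run_val:
                run_len += 1
            else:
                if run_val > 0:
                    entries.append((run_val, run_len))
                run_val, run_len = v, 1
            x, y, z = x + d[0], y + d[1], z + d[2]
        if run_val > 0:
            entries.append((run_val, run_len))
    max_len = max((l for _, l in entries), default=1)
    m = np.zeros((ng, max_len))
    for v, l in entries:
        m[v - 1, l - 1] += 1
    return m


def oracle_zones(levels):
    """BFS flood fill of 26-connected equal-level zones."""
    nx, ny, nz = levels.shape
    seen = np.zeros(levels.shape, bool)
    zones = []
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    for i, j, k in itertools.product(range(nx), range(ny), range(nz)):
        if levels[i, j, k] == 0 or seen[i, j, k]:
            continue
        g = levels[i, j, k]
        stack, members = [(i, j, k)], []
        seen[i, j, k] = True
        while stack:
            c = stack.pop()
            members.append(c)
            for o in offsets:
                x, y, z = c[0] + o[0], c[1] + o[1], c[2] + o[2]
                if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
                    if not seen[x, y, z] and levels[x, y, z] == g:
                        seen[x, y, z] = True
                        stack.append((x, y, z))
        zones.append((g, members))
    return zones


def oracle_taxicab_distance(mask):
    """BFS city-block distance to outside the (padded) mask; border = 1."""
    from collections import deque

    padded = np.pad(mask, 1)
    nx, ny, nz = padded.shape
    dist = np.full(padded.shape, -1, int)
    dq = deque()
    for i, j, k in itertools.product(range(nx), range(ny), range(nz)):
        if not padded[i, j, k]:
            dist[i, j, k] = 0
            dq.append((i, j, k))
    while dq:
        i, j, k = dq.popleft()
        for o in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            x, y, z = i + o[0], j + o[1], k + o[2]
            if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz and dist[x, y, z] < 0:
                dist[x, y, z] = dist[i, j, k] + 1
                dq.append((x, y, z))
    return dist[1:-1, 1:-1, 1:-1]


def random_levels(rng, shape=(6, 6, 6), ng=4, p_zero=0.25):
    lv = rng.integers(1, ng + 1, size=shape)
    lv[rng.random(shape) < p_zero] = 0
    return lv


# ---------------------------------------------------------------------------
# Manifest combinatorics
# ---------------------------------------------------------------------------

class TestManifest:
    def test_default_expansion(self):
        m = build_manifest()
        assert m.n_base == 182
        assert m.n_base_discretised == 118
        assert len(m) == 64 * 4 + 118 * 4 * 8 == 4032

    def test_single_spacing_single_setting_gives_base_set(self):
        cfg = ProcessingConfig(spacings=(2.0,), bin_numbers=(32,), bin_sizes=())
        assert len(build_manifest(cfg)) == 64 + 118 == 182

    def test_two_spacings_fbn_only(self):
        cfg = ProcessingConfig(spacings=(1.0, 2.0), bin_numbers=(8, 16, 32, 64), bin_sizes=())
        assert len(build_manifest(cfg)) == 64 * 2 + 118 * 2 * 4 == 1072

    def test_family_sizes(self):
        sizes = {f: len(v) for f, v in FAMILY_FEATURES.items()}
        assert sizes == {
            "morphological": 29, "local_intensity": 2, "intensity_statistics": 18,
            "intensity_volume_histogram": 15, "intensity_histogram": 23,
            "glcm": 25, "glrlm": 16, "glszm": 16, "gldzm": 16,
            "ngtdm": 5, "ngldm": 17,
        }

    def test_full_ids_are_unique(self):
        ids = build_manifest().full_ids()
        assert len(ids) == len(set(ids))


# ---------------------------------------------------------------------------
# Texture matrices vs oracles
# ---------------------------------------------------------------------------

class TestTextureOracles:
    def test_glcm_matches_brute_force(self, rng):
        for seed in range(4):
            lv = random_levels(np.random.default_rng(seed))
            for d in DIRECTIONS_13:
                np.testing.assert_array_equal(glcm_matrix(lv, 4, d), oracle_glcm(lv, 4, d))

    def test_glcm_checkerboard_hand_count(self):
        # 4x4x1 two-level checkerboard, single in-plane direction (1,0,0):
        # every one of the 12 ordered x-neighbour pairs alternates 1<->2, so
        # the symmetric matrix has 12 counts in each off-diagonal cell.
        lv = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        m = glcm_matrix(lv, 2, (1, 0, 0))
        np.testing.assert_array_equal(m, [[0, 12], [12, 0]])

    def test_glrlm_matches_brute_force(self):
        for seed in range(4):
            lv = random_levels(np.random.default_rng(seed + 10))
            for d in DIRECTIONS_13:
                ours = run_length_matrix(lv, 4, d)
                oracle = oracle_runs(lv, 4, d)
                width = max(ours.shape[1], oracle.shape[1])
                np.testing.assert_array_equal(
                    np.pad(ours, ((0, 0), (0, width - ours.shape[1]))),
                    np.pad(oracle, ((0, 0), (0, width - oracle.shape[1]))),
                )

    def test_glszm_matches_flood_fill_oracle(self):
        for seed in range(4):
            lv = random_levels(np.random.default_rng(seed + 20))
            zones = oracle_zones(lv)
            sizes = sorted((g, len(m)) for g, m in zones)
            ours = glszm_features(lv, 4)
            ns = len(zones)
            nv = int((lv > 0).sum())
            assert ours["zone_percentage"] == pytest.approx(ns / nv)
            oracle_sze = sum(1.0 / s**2 for _, s in sizes) / ns
            assert ours["small_zone_emphasis"] == pytest.approx(oracle_sze)
            oracle_glnu = sum(
                sum(1 for g2, _ in sizes if g2 == g) ** 2
                for g in set(g for g, _ in sizes)
            ) / ns
            assert ours["grey_level_non_uniformity"] == pytest.approx(oracle_glnu)

    def test_gldzm_matches_bfs_oracle(self):
        for seed in range(4):
            r = np.random.default_rng(seed + 30)
            lv = random_levels(r)
            morph = lv > 0
            ours = gldzm_features(lv, 4, morph)
            dist = oracle_taxicab_distance(morph)
            zones = oracle_zones(lv)
            entries = [
                (g, max(1, min(dist[c] for c in members))) for g, members in zones
            ]
            ns = len(entries)
            oracle_sde = sum(1.0 / d**2 for _, d in entries) / ns
            oracle_lde = sum(float(d**2) for _, d in entries) / ns
            assert ours["small_distance_emphasis"] == pytest.approx(oracle_sde)
            assert ours["large_distance_emphasis"] == pytest.approx(oracle_lde)

    def test_ngtdm_matches_voxel_loop_oracle(self):
        for seed in range(3):
            r = np.random.default_rng(seed + 40)
            lv = random_levels(r, shape=(5, 5, 5))
            mask = lv > 0
            nx, ny, nz = lv.shape
            s = np.zeros(5)
            cnt = np.zeros(5)
            for i, j, k in itertools.product(range(nx), range(ny), range(nz)):
                if not mask[i, j, k]:
                    continue
                nb = []
                for o in itertools.product((-1, 0, 1), repeat=3):
                    if o == (0, 0, 0):
                        continue
                    x, y, z = i + o[0], j + o[1], k + o[2]
                    if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz and mask[x, y, z]:
                        nb.append(lv[x, y, z])
                if nb:
                    g = lv[i, j, k]
                    s[g] += abs(g - np.mean(nb))
                    cnt[g] += 1
            n = cnt.sum()
            p = cnt / n
            denom = (p * s).sum()
            oracle_coarseness = 1.0 / denom if denom > 0 else 1e6
            ours = ngtdm_features(lv, 4)
            assert ours["coarseness"] == pytest.approx(oracle_coarseness, rel=1e-9)

    def test_ngldm_matches_voxel_loop_oracle(self):
        for seed in range(3):
            r = np.random.default_rng(seed + 50)
            lv = random_levels(r, shape=(5, 5, 5))
            mask = lv > 0
            nx, ny, nz = lv.shape
            entries = []
            for i, j, k in itertools.product(range(nx), range(ny), range(nz)):
                if not mask[i, j, k]:
                    continue
                dep = 0
                for o in itertools.product((-1, 0, 1), repeat=3):
                    if o == (0, 0, 0):
                        continue
                    x, y, z = i + o[0], j + o[1], k + o[2]
                    if (
                        0 <= x < nx and 0 <= y < ny and 0 <= z < nz
                        and mask[x, y, z] and lv[x, y, z] == lv[i, j, k]
                    ):
                        dep += 1
                entries.append((lv[i, j, k], dep + 1))
            ns = len(entries)
            oracle_lde = sum(1.0 / j**2 for _, j in entries) / ns
            oracle_hde = sum(float(j**2) for _, j in entries) / ns
            ours = ngldm_features(lv, 4)
            assert ours["low_dependence_emphasis"] == pytest.approx(oracle_lde)
            assert ours["high_dependence_emphasis"] == pytest.approx(oracle_hde)
            assert ours["dependence_count_percentage"] == pytest.approx(1.0)

    def test_matrix_normalisations_sum_to_one(self, rng):
        lv = random_levels(rng)
        for d in DIRECTIONS_13[:3]:
            m = glcm_matrix(lv, 4, d)
            assert (m / m.sum()).sum() == pytest.approx(1.0, abs=1e-9)
        ours = ngldm_features(lv, 4)
        # dependence-count energy is the sum of squared probabilities, so the
        # probabilities it derives from summed to 1 by construction
        assert 0.0 < ours["dependence_count_energy"] <= 1.0


# ---------------------------------------------------------------------------
# Whole-image feature behaviour
# ---------------------------------------------------------------------------

def _masks_for(image, mask, cfg=None):
    morph = mask.copy(kind="morphological")
    imask = resegment(image, morph, cfg)
    return morph, imask


@pytest.fixture(scope="module")
def constant_sphere_features(sphere_phantom):
    img, mask = sphere_phantom
    cfg = ProcessingConfig(spacings=(1.0,), bin_numbers=(8,), bin_sizes=(6.0,))
    morph, imask = _masks_for(img, mask, cfg)
    vals, flags = compute_features(img, morph, imask, build_manifest(cfg), cfg)
    return vals, flags


class TestFeatureValues:
    def test_constant_roi_degenerate_limits(self, constant_sphere_features):
        vals, _ = constant_sphere_features
        assert vals["intensity_statistics_variance_1mm"] == 0.0
        assert vals["intensity_histogram_maximum_1mm_fbn8"] == 1.0  # one grey level
        assert vals["glcm_joint_max_1mm_fbn8"] == 1.0
        assert vals["intensity_statistics_mean_1mm"] == 40.0

    def test_sphere_volume_and_sphericity(self, constant_sphere_features):
        vals, _ = constant_sphere_features
        assert vals["morphological_volume_1mm"] == pytest.approx(4189, rel=0.03)
        assert vals["morphological_sphericity_1mm"] >= 0.97

    def test_no_degenerate_flags_on_well_formed_roi(self, textured_phantom):
        img, mask = textured_phantom
        cfg = ProcessingConfig(spacings=(1.0,), bin_numbers=(16,), bin_sizes=(12.0,))
        morph, imask = _masks_for(img, mask, cfg)
        vals, flags = compute_features(img, morph, imask, build_manifest(cfg), cfg)
        assert flags == {}
        assert all(np.isfinite(v) for v in vals.values())

    def test_single_voxel_roi_flags_texture_not_silent_zero(self):
        vox = np.full((9, 9, 9), -50.0)
        vox[4, 4, 4] = 40.0
        img = VolumetricImage(vox, (1, 1, 1))
        labels = np.zeros(vox.shape, bool)
        labels[4, 4, 4] = True
        mask = RoiMask(labels, (1, 1, 1))
        cfg = ProcessingConfig(spacings=(1.0,), bin_numbers=(8,), bin_sizes=())
        morph, imask = _masks_for(img, mask, cfg)
        vals, flags = compute_features(img, morph, imask, build_manifest(cfg), cfg)
        assert np.isnan(vals["glcm_contrast_1mm_fbn8"])
        assert "glcm_contrast_1mm_fbn8" in flags
        assert vals["intensity_statistics_mean_1mm"] == 40.0

    def test_whole_voxel_translation_leaves_features_unchanged(self, textured_phantom):
        img, mask = textured_phantom
        cfg = ProcessingConfig(spacings=(1.0,), bin_numbers=(8,), bin_sizes=())
        manifest = build_manifest(cfg)
        morph, imask = _masks_for(img, mask, cfg)
        vals, _ = compute_features(img, morph, imask, manifest, cfg)
        shift = (3, 2, 1)
        img2 = VolumetricImage(np.roll(img.voxels, shift, (0, 1, 2)), img.spacing)
        mask2 = RoiMask(np.roll(mask.labels, shift, (0, 1, 2)), img.spacing)
        morph2, imask2 = _masks_for(img2, mask2, cfg)
        vals2, _ = compute_features(img2, morph2, imask2, manifest, cfg)
        for key in vals:
            # mesh-derived morphology accrues ~1e-7 relative float noise from
            # smoothing/marching-cubes on the shifted grid; all grid-based
            # features must match to machine precision
            tol = dict(rel=1e-5, abs=1e-8) if key.startswith("morphological") else dict(abs=1e-9)
            assert vals2[key] == pytest.approx(vals[key], **tol), key

    def test_intensity_statistics_rotation_invariant_on_uniform_sphere(self, sphere_phantom):
        from radperturb import rotate

        img, mask = sphere_phantom
        # A soft-tissue re-segmentation window excludes partial-volume
        # boundary voxels, leaving the constant interior in both conditions.
        cfg = ProcessingConfig(spacings=(1.0,), bin_numbers=(8,), bin_sizes=(),
                               resegment_range=(30.0, 50.0))
        manifest = build_manifest(cfg)
        morph, imask = _masks_for(img, mask, cfg)
        base, _ = compute_features(img, morph, imask, manifest, cfg)
        for theta in (7.0, 13.0):
            r_img, r_frac = rotate(img, mask, theta)
            r_mask = r_frac.binarise(0.5)
            morph_r, imask_r = _masks_for(r_img, r_mask, cfg)
            rot, _ = compute_features(r_img, morph_r, imask_r, manifest, cfg)
            for name in ("mean", "variance", "p10", "p90", "median"):
                key = f"intensity_statistics_{name}_1mm"
                assert abs(rot[key] - base[key]) < 0.5, key

    def test_ivh_fraction_features_on_uniform_gradient(self):
        # 100 voxels with intensities 1..100: closed-form volume fractions.
        vox = np.zeros((10, 10, 3))
        vox[:, :, 1] = np.arange(1, 101, dtype=float).reshape(10, 10)
        img = VolumetricImage(vox, (1, 1, 1))
        labels = np.zeros(vox.shape, bool)
        labels[:, :, 1] = True
        mask = RoiMask(labels, (1, 1, 1))
        cfg = ProcessingConfig(spacings=(1.0,), bin_numbers=(8,), bin_sizes=(),
                               resegment_range=(-300, 200))
        morph, imask = _masks_for(img, mask, cfg)
        vals, _ = compute_features(img, morph, imask, build_manifest(cfg), cfg)
        # 10% up the 1..100 range is 10.9; the 90 voxels 11..100 lie above it.
        assert vals["intensity_volume_histogram_v10_1mm"] == pytest.approx(0.90)
        assert vals["intensity_volume_histogram_v90_1mm"] == pytest.approx(0.10)
        assert vals["intensity_volume_histogram_auc_1mm"] == pytest.approx(0.5, abs=0.02)
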