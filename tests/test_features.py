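"""Feature-extraction unit and property tests, including the brute-force
texture-matrix oracles and the wavelet conservation checks."""

import math

import numpy as np
import pytest
from _oracles import (glcm_bruteforce, glcm_features_reference,
                      glrlm_bruteforce, glrlm_features_reference)

from thalrad.errors import (DecompositionError, DegenerateRoiError,
                            ResamplingError)
from thalrad.features import (DIRECTIONS, CooccurrenceMatrix, DiscretizedRoi,
                              FeatureConfig, RoiMask, VoxelGrid,
                              catalog_size, discretize, extract_all,
                              first_order_features, glcm, glcm_features,
                              glrlm, glrlm_features, paper_style_name,
                              resample_mean_pool, run_manifest,
                              shape_features, wavelet_decompose)


def grid_of(values, spacing=(1, 1, 1)):
    return VoxelGrid(np.asarray(values, dtype=float), spacing)


def full_mask(shape):
    return RoiMask(np.ones(shape, dtype=bool))


def random_discretized(rng, shape=(5, 5, 5), n_levels=4, p_mask=0.7):
    mask = rng.random(shape) < p_mask
    levels = np.where(mask, rng.integers(1, n_levels + 1, size=shape), 0)
    return DiscretizedRoi(levels.astype(np.int32), n_levels)


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

class TestResampling:
    def test_block_mean_of_eight_voxels(self):
        g = grid_of(np.arange(1, 9).reshape(2, 2, 2))
        pg, pm = resample_mean_pool(g, full_mask((2, 2, 2)), (2, 2, 2))
        assert pg.values.shape == (1, 1, 1)
        assert pg.values[0, 0, 0] == pytest.approx(4.5)
        assert pm.membership.all()

    def test_constant_grid_stays_constant(self):
        g = grid_of(np.full((4, 4, 4), 7.0))
        pg, _ = resample_mean_pool(g, full_mask((4, 4, 4)), (2, 2, 2))
        assert np.allclose(pg.values, 7.0)

    def test_identity_when_spacing_unchanged(self):
        vals = np.random.default_rng(0).normal(size=(3, 4, 5))
        g = grid_of(vals)
        pg, pm = resample_mean_pool(g, full_mask((3, 4, 5)), (1, 1, 1))
        assert np.array_equal(pg.values, vals)
        assert pm.membership.all()

    def test_minority_block_pools_to_empty_mask(self):
        m = np.zeros((2, 2, 4), dtype=bool)
        m[:, :, :2] = True                     # 8/8 true -> in
        m[0, 0, 2] = True                      # 1/8 true -> out
        _, pm = resample_mean_pool(
            grid_of(np.zeros((2, 2, 4))), RoiMask(m), (2, 2, 2)
        )
        assert pm.membership.ravel().tolist() == [True, False]

    def test_empty_pooled_mask_is_degenerate(self):
        m = np.zeros((2, 2, 2), dtype=bool)
        m[0, 0, 0] = True
        with pytest.raises(DegenerateRoiError):
            resample_mean_pool(grid_of(np.zeros((2, 2, 2))), RoiMask(m),
                               (2, 2, 2))

    def test_non_integer_ratio_rejected(self):
        g = grid_of(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ResamplingError):
            resample_mean_pool(g, full_mask((4, 4, 4)), (1.5, 1, 1))


# --------------------------------------------------------------------------
# discretization
# --------------------------------------------------------------------------

class TestDiscretize:
    def test_two_point_range(self):
        g = grid_of([[[0.0, 10.0]]])
        d = discretize(g, full_mask((1, 1, 2)), 2)
        assert list(d.levels[0, 0]) == [1, 2]

    def test_constant_roi_maps_to_level_one(self):
        g = grid_of(np.full((2, 2, 2), 3.3))
        d = discretize(g, full_mask((2, 2, 2)), 16)
        assert set(d.levels.ravel()) == {1}

    def test_equally_spaced_values_bijective(self):
        vals = np.arange(32, dtype=float).reshape(2, 4, 4)
        d = discretize(grid_of(vals), full_mask((2, 4, 4)), 32)
        assert np.array_equal(np.sort(d.levels.ravel()),
                              np.arange(1, 33))

    def test_levels_bounded_and_sentinel(self, rng):
        mask = rng.random((4, 4, 4)) < 0.5
        mask[0, 0, 0] = True
        g = grid_of(rng.normal(size=(4, 4, 4)))
        d = discretize(g, RoiMask(mask), 8)
        assert d.levels[~mask].max(initial=0) == 0
        inside = d.levels[mask]
        assert inside.min() >= 1 and inside.max() <= 8

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateRoiError):
            discretize(grid_of(np.zeros((2, 2, 2))),
                       RoiMask(np.zeros((2, 2, 2), bool)), 4)


# --------------------------------------------------------------------------
# first-order
# --------------------------------------------------------------------------

class TestFirstOrder:
    def test_hand_values_one_two_three(self):
        g = grid_of([[[1.0, 2.0, 3.0]]])
        f = first_order_features(g, full_mask((1, 1, 3)), n_levels=3)
        assert f["mean"] == pytest.approx(2.0)
        assert f["variance"] == pytest.approx(2 / 3)
        assert f["mad"] == pytest.approx(2 / 3)
        assert f["rms"] == pytest.approx(math.sqrt(14 / 3))
        assert f["range"] == pytest.approx(2.0)
        assert f["skewness"] == pytest.approx(0.0)
        assert f["entropy"] == pytest.approx(math.log2(3))
        assert f["energy"] == pytest.approx(14.0)
        assert f["median"] == pytest.approx(2.0)

    def test_constant_roi_conventions(self):
        g = grid_of(np.full((1, 1, 3), 2.0))
        f = first_order_features(g, full_mask((1, 1, 3)))
        assert f["mean"] == 2 and f["variance"] == 0 and f["range"] == 0
        assert f["entropy"] == 0 and f["uniformity"] == 1
        assert f["skewness"] == 0

    def test_translation_equivariance(self, rng):
        g = grid_of(rng.normal(size=(3, 3, 3)))
        m = full_mask((3, 3, 3))
        f0 = first_order_features(g, m)
        f1 = first_order_features(
            grid_of(g.values + 11.5), m
        )
        assert f1["mean"] == pytest.approx(f0["mean"] + 11.5)
        for k in ("variance", "mad", "range", "skewness", "std",
                  "entropy", "uniformity", "kurtosis"):
            assert f1[k] == pytest.approx(f0[k], abs=1e-9), k

    def test_exactly_fourteen_features(self, rng):
        f = first_order_features(grid_of(rng.normal(size=(3, 3, 3))),
                                 full_mask((3, 3, 3)))
        assert len(f) == 14


# --------------------------------------------------------------------------
# shape
# --------------------------------------------------------------------------

class TestShape:
    def test_single_voxel_cube_closed_forms(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        f = shape_features(RoiMask(m), (2, 2, 2))
        assert f["volume"] == pytest.approx(8.0)
        assert f["surface_area"] == pytest.approx(24.0)
        assert f["surface_to_volume_ratio"] == pytest.approx(3.0)
        assert f["compactness2"] == pytest.approx(math.pi / 6)
        assert f["max_diameter_3d"] == 0.0

    def test_two_voxel_bar(self):
        m = np.zeros((4, 3, 3), bool)
        m[1, 1, 1] = m[2, 1, 1] = True
        f = shape_features(RoiMask(m), (1, 1, 1))
        assert f["volume"] == pytest.approx(2.0)
        assert f["surface_area"] == pytest.approx(10.0)
        assert f["max_diameter_3d"] == pytest.approx(1.0)

    def test_sphericity_disproportion_identity(self, rng):
        for _ in range(5):
            m = rng.random((6, 6, 6)) < 0.4
            m[3, 3, 3] = True
            f = shape_features(RoiMask(m), (1.0, 1.5, 2.0))
            assert f["sphericity"] * f["spherical_disproportion"] == (
                pytest.approx(1.0)
            )

    def test_exactly_eight_features(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        assert len(shape_features(RoiMask(m), (1, 1, 1))) == 8


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

class TestGlcm:
    def test_single_adjacent_pair(self):
        lv = np.zeros((1, 1, 4), np.int32)
        lv[0, 0, 0], lv[0, 0, 1] = 1, 2
        cm = glcm(DiscretizedRoi(lv, 2), DIRECTIONS[2])   # (0,0,1)
        assert np.allclose(cm.probabilities, [[0, 0.5], [0.5, 0]])

    def test_constant_roi_single_cell(self):
        lv = np.ones((1, 1, 3), np.int32)
        cm = glcm(DiscretizedRoi(lv, 2), DIRECTIONS[2])
        f = glcm_features(cm)
        assert f["energy"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)
        assert f["correlation"] == 1.0

    def test_no_valid_pair_flagged_empty(self):
        lv = np.zeros((3, 3, 3), np.int32)
        lv[1, 1, 1] = 1
        cm = glcm(DiscretizedRoi(lv, 2), DIRECTIONS[0])
        assert cm.empty
        f = glcm_features(cm)
        assert f["correlation"] == 1.0 and f["energy"] == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_bruteforce_oracle_all_directions(self, seed):
        rng = np.random.default_rng(seed)
        disc = random_discretized(rng)
        for off in DIRECTIONS:
            got = glcm(disc, off)
            want = glcm_bruteforce(disc.levels, off.delta, disc.n_levels)
            assert np.array_equal(got.counts, want), off.delta

    def test_symmetry_and_normalization(self, rng):
        disc = random_discretized(rng, shape=(6, 6, 6))
        for off in DIRECTIONS:
            cm = glcm(disc, off)
            assert np.array_equal(cm.counts, cm.counts.T)
            if not cm.empty:
                assert cm.probabilities.sum() == pytest.approx(1.0)

    def test_feature_hand_values(self):
        cm = CooccurrenceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]),
                                DIRECTIONS[0])
        f = glcm_features(cm)
        assert f["max_prob"] == pytest.approx(0.5)
        assert f["energy"] == pytest.approx(0.5)
        assert f["dissimilarity"] == pytest.approx(1.0)
        assert f["correlation"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_features_match_formula_reference(self, seed):
        rng = np.random.default_rng(100 + seed)
        disc = random_discretized(rng, n_levels=5)
        cm = glcm(disc, DIRECTIONS[seed % 13])
        if cm.empty:
            pytest.skip("degenerate draw")
        got = glcm_features(cm)
        want = glcm_features_reference(cm.probabilities)
        for k, v in got.items():
            assert v == pytest.approx(want[k], rel=1e-10, abs=1e-12), k


# --------------------------------------------------------------------------
# GLRLM
# --------------------------------------------------------------------------

class TestGlrlm:
    def test_hand_run_enumeration(self):
        lv = np.zeros((1, 1, 3), np.int32)
        lv[0, 0] = [1, 1, 2]
        m = glrlm(DiscretizedRoi(lv, 2), DIRECTIONS[2])
        assert m.counts[0, 1] == 1          # level 1, length 2
        assert m.counts[1, 0] == 1          # level 2, length 1

    def test_constant_line_single_run(self):
        lv = np.zeros((1, 1, 6), np.int32)
        lv[0, 0] = 3
        m = glrlm(DiscretizedRoi(lv, 4), DIRECTIONS[2])
        f = glrlm_features(m)
        n = 6
        assert f["sre"] == pytest.approx(1 / n**2)
        assert f["lre"] == pytest.approx(n**2)
        assert f["rp"] == pytest.approx(1 / n)

    def test_feature_hand_values(self):
        counts = np.zeros((2, 2), dtype=int)
        counts[0, 1] = 1                     # level 1 length 2
        counts[1, 0] = 1                     # level 2 length 1
        from thalrad.features import RunLengthMatrix

        f = glrlm_features(RunLengthMatrix(counts, DIRECTIONS[0]))
        assert f["sre"] == pytest.approx(0.625)
        assert f["rln"] == pytest.approx(1.0)
        assert f["rp"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(25))
    def test_bruteforce_oracle_all_directions(self, seed):
        rng = np.random.default_rng(1000 + seed)
        disc = random_discretized(rng)
        for off in DIRECTIONS:
            got = glrlm(disc, off).counts
            want = glrlm_bruteforce(disc.levels, off.delta, disc.n_levels)
            assert got.shape == want.shape and np.array_equal(got, want), (
                off.delta
            )

    def test_conservation_every_direction(self, rng):
        disc = random_discretized(rng, shape=(7, 6, 5), n_levels=6)
        n_roi = (disc.levels > 0).sum()
        for off in DIRECTIONS:
            m = glrlm(disc, off)
            l = np.arange(1, m.counts.shape[1] + 1)
            assert (m.counts * l).sum() == n_roi

    @pytest.mark.parametrize("seed", range(10))
    def test_features_match_formula_reference(self, seed):
        rng = np.random.default_rng(2000 + seed)
        disc = random_discretized(rng, n_levels=5)
        m = glrlm(disc, DIRECTIONS[(seed * 3) % 13])
        got = glrlm_features(m)
        want = glrlm_features_reference(m.counts)
        for k, v in got.items():
            assert v == pytest.approx(want[k], rel=1e-12), k


# --------------------------------------------------------------------------
# wavelet
# --------------------------------------------------------------------------

class TestWavelet:
    def test_constant_image_detail_free(self):
        g = grid_of(np.full((8, 8, 8), 5.0))
        st = wavelet_decompose(g, "haar")
        for label, ch in zip(st.subband_labels[1:], st.channels[1:]):
            if "H" in label:
                assert np.allclose(ch.values, 0.0, atol=1e-12), label
            else:
                assert np.allclose(ch.values, 5.0, atol=1e-12)

    def test_energy_conservation(self, rng):
        x = rng.normal(size=(12, 16, 12))
        st = wavelet_decompose(grid_of(x), "coif1")
        e0 = (x**2).sum()
        es = sum((c.values**2).sum() for c in st.channels[1:])
        assert abs(es - e0) / e0 < 1e-6

    def test_subbands_reconstruct_original(self, rng):
        x = rng.normal(size=(10, 12, 14))
        st = wavelet_decompose(grid_of(x), "coif1")
        recon = sum(c.values for c in st.channels[1:])
        assert np.max(np.abs(recon - x)) / np.max(np.abs(x)) < 1e-6

    def test_too_small_grid_rejected(self):
        with pytest.raises(DecompositionError):
            wavelet_decompose(grid_of(np.zeros((4, 8, 8))), "coif1")


# --------------------------------------------------------------------------
# full extraction
# --------------------------------------------------------------------------

SMALL = FeatureConfig(
    n_levels=8, channels=(1, 2),
    glcm_features=("correlation", "energy"), glrlm_features=("sre",),
)


class TestExtractAll:
    def test_deterministic_and_names_stable(self, rng):
        vals = rng.normal(size=(10, 10, 10))
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 2:8] = True
        g, m = grid_of(vals), RoiMask(mask)
        f1 = extract_all(g, m, SMALL)
        f2 = extract_all(g, m, SMALL)
        assert f1 == f2
        g2 = grid_of(rng.normal(size=(10, 10, 10)))
        assert list(extract_all(g2, m, SMALL)) == list(f1)

    def test_catalog_size_formula(self):
        f = extract_all(
            grid_of(np.random.default_rng(1).normal(size=(10, 10, 10))),
            RoiMask(np.pad(np.ones((6, 6, 6), bool), 2)), SMALL
        )
        expected = 8 + 2 * (14 + (2 + 1) * 14)
        assert len(f) == expected == catalog_size(SMALL)
        assert catalog_size(FeatureConfig()) == 8 + 9 * (14 + 30 * 14)

    def test_intensity_shift_leaves_texture_unchanged(self, rng):
        vals = rng.normal(size=(10, 10, 10))
        mask = np.pad(np.ones((6, 6, 6), bool), 2)
        f0 = extract_all(grid_of(vals), RoiMask(mask), SMALL)
        f1 = extract_all(grid_of(vals + 100.0), RoiMask(mask), SMALL)
        for k in f0:
            fam = k.split(".")[1] if not k.startswith("shape") else "shape"
            if fam in ("glcm", "glrlm") and k.startswith("W1."):
                assert f1[k] == pytest.approx(f0[k], abs=1e-9), k

    def test_rotation_permutes_directions(self, rng):
        """A 90-degree rotation permutes the 13 direction axes; per-direction
        texture values follow that permutation and _mean values are
        invariant."""
        config = FeatureConfig(
            n_levels=8, channels=(1,),
            glcm_features=("correlation", "energy"),
            glrlm_features=("sre",),
        )
        vals = rng.normal(size=(10, 10, 10))
        mask = np.pad(np.ones((6, 6, 6), bool), 2)
        f0 = extract_all(grid_of(vals), RoiMask(mask), config)
        # rotate 90 degrees in the (axis1, axis2) plane
        f1 = extract_all(
            grid_of(np.rot90(vals, axes=(1, 2)).copy()),
            RoiMask(np.rot90(mask, axes=(1, 2)).copy()), config,
        )
        # rot90(axes=(1,2)): new[i, j, k] = old[i, k, N-1-j]
        # => an offset (a, b, c) in the original maps to (a, -c, b)
        def rotated_index(off):
            d = (off.delta[0], -off.delta[2], off.delta[1])
            first = next(x for x in d if x != 0)
            if first < 0:
                d = tuple(-x for x in d)
            return next(o.index for o in DIRECTIONS if o.delta == d)

        for off in DIRECTIONS:
            j = rotated_index(off)
            for fam, feat in (("glcm", "correlation"), ("glcm", "energy"),
                              ("glrlm", "sre")):
                a = f0[f"W1.{fam}.{feat}_{off.index}"]
                b = f1[f"W1.{fam}.{feat}_{j}"]
                assert b == pytest.approx(a, rel=1e-10), (off.delta, fam)
        for fam, feat in (("glcm", "correlation"), ("glrlm", "sre")):
            assert f1[f"W1.{fam}.{feat}_mean"] == pytest.approx(
                f0[f"W1.{fam}.{feat}_mean"], rel=1e-10
            )
        for k in f0:
            if ".firstorder." in k:
                assert f1[k] == pytest.approx(f0[k], rel=1e-9), k

    def test_manifest_and_paper_aliases(self):
        man = run_manifest(SMALL)
        assert man["catalog_size"] == catalog_size(SMALL)
        assert man["channel_map"]["W2"] == "LLL"
        assert paper_style_name("W6.glcm.correlation_7") == "W6.Co_Corr_7"
        assert paper_style_name("W1.firstorder.median") == "W1.Mid"
        assert paper_style_name("W5.glrlm.rln_9") == "W5.RLN_9"
        assert paper_style_name("shape.surface_to_volume_ratio") == "SVR"
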