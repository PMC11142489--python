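"""Radiomics: every feature family against explicit voxel/pair
enumeration oracles on tiny arrays, filter semantics, extraction
determinism and the forest-fusion contract."""

import math

import numpy as np
import pytest
import pywt

from gliopipe.phantom import PhantomSpec, generate_cohort
from gliopipe.radiomics import (
    OFFSETS_13,
    RadiomicsConfig,
    apply_filters,
    discretize,
    extract_combination,
    first_order_features,
    glcm_features,
    shape_features,
    square_filter,
    train_radiomics,
)


def glcm_oracle(levels, mask, offsets):
    """Brute-force symmetric co-occurrence counting by nested loops."""
    counts = {}
    D, H, W = levels.shape
    for z in range(D):
        for y in range(H):
            for x in range(W):
                if not mask[z, y, x]:
                    continue
                for dz, dy, dx in offsets:
                    z2, y2, x2 = z + dz, y + dy, x + dx
                    if 0 <= z2 < D and 0 <= y2 < H and 0 <= x2 < W and mask[z2, y2, x2]:
                        a, b = levels[z, y, x], levels[z2, y2, x2]
                        counts[(a, b)] = counts.get((a, b), 0) + 1
                        counts[(b, a)] = counts.get((b, a), 0) + 1
    total = sum(counts.values())
    lmax = int(levels[mask].max())
    p = np.zeros((lmax, lmax))
    for (a, b), c in counts.items():
        p[a - 1, b - 1] = c / total
    return p


def glcm_features_oracle(p):
    L = p.shape[0]
    energy = float((p**2).sum())
    entropy = -sum(v * math.log2(v) for v in p.ravel() if v > 0)
    contrast = sum(p[i, j] * (i - j) ** 2 for i in range(L) for j in range(L))
    mu = sum((i + 1) * p[i, j] for i in range(L) for j in range(L))
    var = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(L) for j in range(L))
    if var > 0:
        corr = sum(p[i, j] * (i + 1 - mu) * (j + 1 - mu) for i in range(L) for j in range(L)) / var
    else:
        corr = 1.0
    homog = sum(p[i, j] / (1 + abs(i - j)) for i in range(L) for j in range(L))
    return {"glcm_energy": energy, "glcm_entropy": entropy, "glcm_contrast": contrast,
            "glcm_correlation": corr, "glcm_homogeneity": homog}


class TestDiscretize:
    def test_floor_arithmetic(self):
        vol = np.zeros((1, 1, 4))
        vol[0, 0] = [0, 24.9, 25, 50]
        mask = np.ones((1, 1, 4), bool)
        levels, n = discretize(vol, mask, 25)
        np.testing.assert_array_equal(levels[0, 0], [1, 1, 2, 3])
        assert n == 3

    def test_constant_region_single_level(self):
        levels, n = discretize(np.full((2, 2, 2), 7.0), np.ones((2, 2, 2), bool), 25)
        assert n == 1 and set(levels.ravel()) == {1}

    def test_doubling_width_never_increases_levels(self, rng):
        vol = rng.normal(0, 50, size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) < 0.7
        for w in (5.0, 10.0, 20.0):
            _, n1 = discretize(vol, mask, w)
            _, n2 = discretize(vol, mask, 2 * w)
            assert n2 <= n1

    def test_level_count_tracks_range(self, rng):
        vol = rng.uniform(0, 100, size=(5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        _, n = discretize(vol, mask, 10.0)
        assert n == math.floor(np.ptp(vol) / 10.0) + 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            discretize(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool), 10)


class TestFirstOrder:
    def test_textbook_moments(self):
        vol = np.zeros((1, 1, 5))
        vol[0, 0] = [1, 2, 3, 4, 5]
        mask = np.ones((1, 1, 5), bool)
        f = first_order_features(vol, mask)
        assert f["mean"] == pytest.approx(3.0)
        assert f["sd"] == pytest.approx(math.sqrt(2.0))
        assert f["energy"] == pytest.approx(55.0)

    def test_symmetric_distribution_zero_skew(self):
        vol = np.zeros((1, 1, 6))
        vol[0, 0] = [-3, -1, -1, 1, 1, 3]
        f = first_order_features(vol, np.ones((1, 1, 6), bool))
        assert abs(f["skewness"]) < 1e-12

    def test_constant_region_zero_entropy(self):
        f = first_order_features(np.full((2, 2, 2), 4.2), np.ones((2, 2, 2), bool))
        assert f["entropy"] == 0.0

    def test_singleton_mask_rejected(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="at least 2"):
            first_order_features(np.ones((2, 2, 2)), mask)

    def test_moments_match_loop_oracle(self, rng):
        vol = rng.normal(10, 5, size=(3, 3, 3))
        mask = rng.random((3, 3, 3)) < 0.8
        f = first_order_features(vol, mask, bin_width=2.0)
        vals = [vol[i] for i in np.ndindex(3, 3, 3) if mask[i]]
        n = len(vals)
        mu = sum(vals) / n
        sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / n)
        assert f["mean"] == pytest.approx(mu)
        assert f["sd"] == pytest.approx(sd)
        assert f["skewness"] == pytest.approx(sum((v - mu) ** 3 for v in vals) / n / sd**3)
        assert f["kurtosis"] == pytest.approx(sum((v - mu) ** 4 for v in vals) / n / sd**4)


class TestGlcm:
    def test_constant_region(self):
        levels = np.ones((2, 2, 1), dtype=np.int64)
        f = glcm_features(levels, np.ones((2, 2, 1), bool))
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_energy"] == 1.0

    def test_checkerboard_contrast_along_axis(self):
        levels = np.indices((4, 1, 1)).sum(axis=0) % 2 + 1
        f = glcm_features(levels, np.ones((4, 1, 1), bool), offsets=[(1, 0, 0)])
        assert f["glcm_contrast"] == pytest.approx(1.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(5):
            levels = rng.integers(1, 5, size=(4, 4, 4))
            mask = rng.random((4, 4, 4)) < 0.75
            if mask.sum() < 4:
                continue
            got = glcm_features(levels, mask)
            expected = glcm_features_oracle(glcm_oracle(levels, mask, OFFSETS_13))
            for k in got:
                assert got[k] == pytest.approx(expected[k], rel=1e-10), k

    def test_no_pairs_rejected(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = True  # isolated voxel: no co-occurring pair
        with pytest.raises(ValueError):
            glcm_features(np.ones((3, 3, 3), dtype=np.int64), mask)


class TestShape:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = shape_features(mask, (1, 1, 1))
        assert f["volume_mm3"] == 1.0
        assert f["surface_mm2"] == 6.0
        assert f["max_diameter_mm"] == 0.0

    def test_bar_exposed_faces(self):
        mask = np.zeros((4, 2, 2), bool)
        mask[1:3, 0, 0] = True
        f = shape_features(mask, (1, 1, 1))
        assert f["volume_mm3"] == 2.0
        assert f["surface_mm2"] == 10.0

    def test_cube_diameter(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        f = shape_features(mask, (1, 1, 1))
        assert f["max_diameter_mm"] == pytest.approx(2 * math.sqrt(3))

    def test_translation_invariance(self, rng):
        mask = np.zeros((8, 8, 8), bool)
        mask[1:4, 1:3, 1:4] = rng.random((3, 2, 3)) < 0.7
        mask[1, 1, 1] = True
        a = shape_features(mask, (1, 2, 0.5))
        b = shape_features(np.roll(mask, (2, 3, 1), axis=(0, 1, 2)), (1, 2, 0.5))
        for k in a:
            assert a[k] == pytest.approx(b[k])

    def test_anisotropic_spacing(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = True
        f = shape_features(mask, (2.0, 1.0, 0.5))
        assert f["volume_mm3"] == pytest.approx(1.0)
        assert f["surface_mm2"] == pytest.approx(2 * (1 * 0.5 + 2 * 0.5 + 2 * 1))


class TestFilters:
    def test_square_before_rescale(self):
        out = square_filter(np.array([-2.0, 3.0]), rescale=False)
        np.testing.assert_array_equal(out, [4.0, 9.0])

    def test_square_rescaled_to_input_range(self, rng):
        x = rng.normal(size=(4, 4, 4))
        y = square_filter(x)
        assert y.min() == pytest.approx(x.min())
        assert y.max() == pytest.approx(x.max())

    def test_log_of_constant_is_zero(self):
        out = apply_filters(np.full((8, 8, 8), 3.0))
        for name in out:
            if name.startswith("log-"):
                assert np.abs(out[name]).max() < 1e-8

    def test_wavelet_lll_dc_gain_on_constant(self):
        cfg = RadiomicsConfig()
        out = apply_filters(np.full((8, 8, 8), 2.0), cfg)
        dec_lo = pywt.Wavelet(cfg.wavelet).dec_lo
        gain = sum(dec_lo) ** 3
        np.testing.assert_allclose(out["wavelet-LLL"], 2.0 * gain, rtol=1e-10)

    def test_filter_catalogue_names(self):
        out = apply_filters(np.zeros((8, 8, 8)))
        assert "original" in out and "square" in out
        assert sum(n.startswith("wavelet-") for n in out) == 8
        assert sum(n.startswith("log-") for n in out) == 2


@pytest.fixture(scope="module")
def study():
    return generate_cohort(1, PhantomSpec(grid_shape=(32, 32, 32)), seed=8)[0].study


class TestExtraction:
    def test_deterministic_and_correct_length(self, study):
        cfg = RadiomicsConfig()
        a = extract_combination(study, "T1CE", "TC", cfg)
        b = extract_combination(study, "T1CE", "TC", cfg)
        assert a.equals(b)
        n_filters = 1 + len(cfg.log_sigmas) + 8 + 1
        assert len(a) == n_filters * 11 + 3  # 6 first-order + 5 GLCM per filter, 3 shape

    def test_tc_volume_within_wt(self, study):
        tc = extract_combination(study, "FLAIR", "TC")["FLAIR|TC|shape|volume_mm3"]
        wt = extract_combination(study, "FLAIR", "WT")["FLAIR|WT|shape|volume_mm3"]
        assert tc <= wt

    def test_empty_mask_flagged(self, study):
        from gliopipe.volume_io import LesionLabelMap, MultiSequenceStudy

        empty = MultiSequenceStudy(
            "empty", study.sequences,
            labels=LesionLabelMap(np.zeros(study.shape, dtype=np.int16)), grade="nonGBM",
        )
        with pytest.raises(ValueError, match="empty"):
            extract_combination(empty, "T1CE", "TC")


class TestTrainRadiomics:
    def test_fused_score_is_mean_of_combinations(self, cohort_small):
        cohort = cohort_small[:4] + cohort_small[10:14]
        cfg = RadiomicsConfig(rf_trees=25, seed=0, test_fraction=0.25)
        res = train_radiomics(cohort, cfg)
        assert all(0.0 <= s <= 1.0 for s in res.scores.values())
        sid = res.heldout_ids[0]
        mean_probs = np.mean([res.extra["combination_probs"][c][sid] for c in cfg.combinations])
        assert res.scores[sid] == pytest.approx(mean_probs)

    def test_degenerate_class_balance_rejected(self, cohort_small):
        with pytest.raises(ValueError, match="per class"):
            train_radiomics(cohort_small[:4], RadiomicsConfig(rf_trees=10))
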