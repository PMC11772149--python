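"""Colour clustering, class areas, collagen compactness, and the DHI."""

import numpy as np
import pandas as pd
import pytest

from cordmetrics import (
    ClassRule,
    ParameterError,
    bin_compactness,
    blue_intensity,
    classify_clusters,
    cluster_colors,
    compactness,
    compute_dhi,
    positive_area_fraction,
    quantify_areas,
)
from cordmetrics.histology import (
    INTENSITY_SCALE,
    PixelClassMap,
    TissueClass,
    classify_centroid,
)
from conftest import brute_force_compactness


def _flat_image(colors, tile=8):
    """One flat tile per colour, stacked horizontally."""
    cols = [np.full((tile, tile, 3), c, dtype=np.uint8) for c in colors]
    return np.concatenate(cols, axis=1)


class TestClustering:
    def test_two_flat_colors_recovered_exactly(self):
        img = _flat_image([(10, 20, 30), (200, 150, 100)])
        model = cluster_colors(img, k=2, seed=0)
        got = set(map(tuple, np.rint(model.centroids).astype(int)))
        assert got == {(10, 20, 30), (200, 150, 100)}
        # nearest-centroid invariant: label of every pixel is its colour
        left = model.labels[:, :8]
        right = model.labels[:, 8:]
        assert len(np.unique(left)) == 1 and len(np.unique(right)) == 1
        assert left[0, 0] != right[0, 0]

    def test_sixteen_palette_centroids_coincide(self):
        rng = np.random.default_rng(0)
        palette = rng.integers(0, 256, (16, 3))
        img = _flat_image([tuple(c) for c in palette])
        model = cluster_colors(img, k=16, seed=1)
        got = sorted(map(tuple, np.rint(model.centroids).astype(int)))
        assert got == sorted(map(tuple, palette))

    def test_k_exceeding_distinct_colors_rejected(self):
        img = _flat_image([(0, 0, 0), (255, 255, 255)])
        with pytest.raises(ParameterError):
            cluster_colors(img, k=3)

    def test_labels_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        m1 = cluster_colors(img, k=8, seed=5)
        m2 = cluster_colors(img, k=8, seed=5)
        assert np.array_equal(m1.labels, m2.labels)
        assert np.array_equal(m1.centroids, m2.centroids)


class TestClassRule:
    @pytest.mark.parametrize("rgb,expected", [
        ((0, 0, 255), TissueClass.COLLAGEN),
        ((255, 255, 255), TissueClass.BACKGROUND),
        ((165, 70, 150), TissueClass.TISSUE),
        ((20, 20, 20), TissueClass.SCAFFOLD),
    ])
    def test_colour_families(self, rgb, expected):
        cls, how, _ = classify_centroid(np.array(rgb, float), ClassRule())
        assert cls == expected

    def test_dark_centroid_without_scaffold_flagged(self):
        rule = ClassRule(scaffold_present=False)
        cls, how, note = classify_centroid(np.array([20, 20, 20], float), rule)
        assert cls == TissueClass.TISSUE
        assert "flagged" in note

    def test_audit_table_covers_every_centroid(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (24, 24, 3)).astype(np.uint8)
        model = cluster_colors(img, k=6, seed=1)
        cm = classify_clusters(model)
        assert len(cm.class_rule) == 6
        assert set(cm.class_rule["class"]).issubset(
            {c.name for c in TissueClass})


def _classmap(classes):
    classes = np.asarray(classes, dtype=np.uint8)
    return PixelClassMap(classes=classes, class_rule=pd.DataFrame())


class TestAreas:
    def test_direct_ratio(self):
        classes = np.zeros((100, 100), dtype=np.uint8)
        classes.ravel()[:4000] = TissueClass.COLLAGEN
        classes.ravel()[4000:6000] = TissueClass.TISSUE
        rep = quantify_areas(_classmap(classes), pixel_size=1.0)
        assert rep.blue_purple_ratio == pytest.approx(2.0)
        assert rep.area_per_class["COLLAGEN"] == 4000.0
        assert sum(rep.area_per_class.values()) == 10000.0

    def test_all_background_ratio_undefined(self):
        rep = quantify_areas(_classmap(np.zeros((10, 10))), pixel_size=2.0)
        assert not rep.ratio_defined and np.isnan(rep.blue_purple_ratio)
        assert rep.excluded_background == 400.0


class TestBlueIntensity:
    def test_white_and_black_limits(self):
        img = np.zeros((1, 2, 3), dtype=np.uint8)
        img[0, 0] = 255  # white collagen pixel -> zero stain
        img[0, 1] = 0    # black -> full stain
        classes = np.full((1, 2), TissueClass.COLLAGEN, dtype=np.uint8)
        inten = blue_intensity(img, _classmap(classes))
        assert inten[0, 0] == 0.0
        assert inten[0, 1] == 1.0

    def test_linear_complement_of_luminance(self, rng):
        img = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
        classes = np.full((8, 8), TissueClass.COLLAGEN, dtype=np.uint8)
        inten = blue_intensity(img, _classmap(classes))
        ii = img.astype(np.int64)
        lum = 299 * ii[..., 0] + 587 * ii[..., 1] + 114 * ii[..., 2]
        assert np.array_equal(inten, (INTENSITY_SCALE - lum) / INTENSITY_SCALE)

    def test_non_collagen_is_zero(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        inten = blue_intensity(img, _classmap(np.zeros((4, 4))))
        assert np.all(inten == 0)


class TestCompactness:
    def test_isolated_pixel_keeps_own_value(self):
        inten = np.zeros((5, 5))
        inten[2, 2] = 1.0
        cm = compactness(inten, radius=1)
        assert cm.values[2, 2] == 1.0

    def test_full_block_center_sums_nine(self):
        inten = np.ones((3, 3))
        cm = compactness(inten, radius=1)
        assert cm.values[1, 1] == 9.0
        assert cm.values[0, 0] == 4.0  # border pixels use in-image window

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            h, w = rng.integers(3, 64, 2)
            inten = rng.random((h, w)) * (rng.random((h, w)) < 0.6)
            mask = inten > 0
            r = int(rng.integers(1, 4))
            got = compactness(inten, r, mask).values
            assert np.array_equal(got, brute_force_compactness(inten, r, mask))

    def test_adding_neighbors_never_decreases(self, rng):
        inten = rng.random((16, 16)) * (rng.random((16, 16)) < 0.4)
        mask = inten > 0
        before = compactness(inten, 1, mask).values
        grown = inten.copy()
        empty = np.argwhere(~mask)
        for i, j in empty[:20]:
            grown[i, j] = rng.random()
        after = compactness(grown, 1, grown > 0).values
        assert np.all(after[mask] >= before[mask])

    def test_invalid_radius(self):
        with pytest.raises(ParameterError):
            compactness(np.ones((3, 3)), radius=0)


class TestCompactnessBinning:
    def test_uniform_map_all_top_level(self):
        cm = compactness(np.full((8, 8), 0.5), radius=1,
                         mask=np.ones((8, 8), bool))
        hist = bin_compactness(cm)
        # border effects spread values; the maximum (interior) value
        # defines the top bin, lower border values fall below
        assert hist.level_fractions.sum() == pytest.approx(1.0)
        interior = compactness(np.full((20, 20), 0.5), radius=1,
                               mask=np.ones((20, 20), bool))
        h2 = bin_compactness(interior)
        assert h2.level_fractions[3] > 0.5

    def test_two_value_split(self):
        # two isolated collagen pixels with intensities c and c/10 fall in
        # the 75-100 % and 0-25 % levels respectively
        inten = np.zeros((5, 9))
        inten[2, 1] = 1.0
        inten[2, 7] = 0.1
        cm = compactness(inten, radius=1, mask=inten > 0)
        hist = bin_compactness(cm)
        assert hist.level_fractions[0] == pytest.approx(0.5)
        assert hist.level_fractions[3] == pytest.approx(0.5)
        assert hist.level_fractions.sum() == pytest.approx(1.0)

    def test_fractions_sum_to_one_random(self, rng):
        for _ in range(5):
            inten = rng.random((12, 12)) * (rng.random((12, 12)) < 0.5)
            cm = compactness(inten, 1, inten > 0)
            hist = bin_compactness(cm)
            if not hist.empty:
                assert hist.level_fractions.sum() == pytest.approx(1.0)

    def test_no_collagen_flagged_empty(self):
        cm = compactness(np.zeros((4, 4)), 1, np.zeros((4, 4), bool))
        assert bin_compactness(cm).empty


class TestPositiveArea:
    def test_limits_and_truth_count(self, rng):
        img = np.zeros((10, 10))
        img[:, :5] = 2.0
        assert positive_area_fraction(img, 0.0) == 100.0
        assert positive_area_fraction(img, 2.0) == 50.0
        mask = (rng.random((100, 100)) < 0.37).astype(float)
        frac = mask.mean() * 100
        assert positive_area_fraction(mask, 1.0) == pytest.approx(frac)

    def test_threshold_out_of_range(self):
        with pytest.raises(ParameterError):
            positive_area_fraction(np.zeros((4, 4)), 5.0)


class TestDHI:
    def test_exactly_uniform_coverage_scores_zero(self):
        res = compute_dhi(np.full((64, 64), 0.4))
        assert res.defined
        assert abs(res.dhi) < 1e-9
        assert np.all(np.abs(res.per_scale_heterogeneity) < 1e-12)

    def test_corner_concentration_scores_higher(self, rng):
        n = 256
        corner = np.zeros((64, 64))
        corner[:16, :16] = 1.0  # 256 pixels in one corner
        scattered = np.zeros(64 * 64)
        scattered[rng.choice(64 * 64, n, replace=False)] = 1.0
        scattered = scattered.reshape(64, 64)
        assert corner.sum() == scattered.sum()
        assert compute_dhi(corner).dhi > compute_dhi(scattered).dhi

    def test_invariant_to_block_permutation(self, rng):
        s = 8
        tiles = rng.random((4, 4)) < 0.5
        mask = np.kron(tiles, np.ones((s, s)))
        perm = rng.permutation(16)
        shuffled = np.kron(tiles.ravel()[perm].reshape(4, 4), np.ones((s, s)))
        a = compute_dhi(mask, [s]).dhi
        b = compute_dhi(shuffled, [s]).dhi
        assert a == pytest.approx(b)

    def test_empty_mask_undefined(self):
        res = compute_dhi(np.zeros((32, 32)))
        assert not res.defined and np.isnan(res.dhi)

    def test_bad_sizes_rejected(self):
        with pytest.raises(ParameterError):
            compute_dhi(np.ones((16, 16)), [1])
        with pytest.raises(ParameterError):
            compute_dhi(np.ones((16, 16)), [32])
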