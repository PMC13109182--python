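import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.morphology import disk, opening

from quando.preprocess import (
    count_foci,
    damage_mask,
    isodata_threshold,
    rolling_ball_subtract,
    segment_nuclei,
)
from quando.types import BinaryMask, CountMask

from conftest import (
    disc_mask,
    flood_fill_labels,
    isodata_fixed_points,
    make_damage,
    make_dna,
)


class TestIsodataThreshold:
    def test_two_level_midpoint(self):
        img = np.concatenate([np.full(500, 10.0), np.full(500, 110.0)])
        img = img.reshape(25, 40)
        t = isodata_threshold(img, n_bins=256)
        bin_width = 100.0 / 256
        assert abs(t - 60.0) <= bin_width

    def test_tri_level_matches_fixed_point_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.choice([0.0, 100.0, 200.0], size=(50, 40), p=[0.9, 0.05, 0.05])
        vals[0, 0], vals[0, 1] = 100.0, 200.0  # guarantee all three levels
        t = isodata_threshold(vals, n_bins=256)
        hits, width = isodata_fixed_points(vals, n_bins=256)
        assert hits, "oracle found no fixed point"
        assert min(abs(t - h) for h in hits) <= 2 * width

    @given(
        lo=st.floats(0, 50), gap=st.floats(10, 500), frac=st.floats(0.1, 0.9),
    )
    @settings(max_examples=30, deadline=None)
    def test_threshold_splits_both_classes_nonempty(self, lo, gap, frac):
        n = 400
        k = int(n * frac)
        img = np.concatenate([np.full(k, lo), np.full(n - k, lo + gap)]).reshape(20, 20)
        t = isodata_threshold(img)
        assert (img <= t).any() and (img > t).any()

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="degenerate histogram"):
            isodata_threshold(np.full((16, 16), 5.0))

    def test_empty_image_raises(self):
        with pytest.raises(ValueError):
            isodata_threshold(np.empty((0, 0)))

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 100, (40, 40))
        assert isodata_threshold(img) == isodata_threshold(img)


class TestSegmentNuclei:
    def test_three_discs(self, three_disc_scene):
        cm = segment_nuclei(three_disc_scene, min_area_px=50, exclude_border=True)
        assert cm.n_objects == 3

    def test_min_area_dominates(self, three_disc_scene):
        cm = segment_nuclei(three_disc_scene, min_area_px=10_000)
        assert cm.n_objects == 0
        assert not cm.labels.any()

    def test_labels_match_flood_fill_oracle(self):
        rng = np.random.default_rng(11)
        img = np.full((80, 80), 5.0)
        for _ in range(6):
            c = rng.integers(10, 70, 2)
            img[disc_mask((80, 80), c, int(rng.integers(3, 7)))] = 150.0
        cm = segment_nuclei(make_dna(img), min_area_px=1, exclude_border=False)
        oracle_labels, oracle_n = flood_fill_labels(img > 75.0)
        assert cm.n_objects == oracle_n
        # identical partitions up to renumbering
        for lab in range(1, cm.n_objects + 1):
            region = cm.labels == lab
            oracle_vals = np.unique(oracle_labels[region])
            assert oracle_vals.size == 1 and oracle_vals[0] > 0
            assert np.array_equal(region, oracle_labels == oracle_vals[0])

    def test_idempotent_relabeling(self, three_disc_scene):
        a = segment_nuclei(three_disc_scene, min_area_px=50)
        b = segment_nuclei(three_disc_scene, min_area_px=50)
        assert np.array_equal(a.labels, b.labels)

    def test_border_exclusion_flag(self):
        img = np.full((64, 64), 5.0)
        img[disc_mask((64, 64), (0, 30), 8)] = 150.0  # touches top border
        img[disc_mask((64, 64), (40, 30), 8)] = 150.0
        kept = segment_nuclei(make_dna(img), min_area_px=10, exclude_border=True)
        all_objs = segment_nuclei(make_dna(img), min_area_px=10, exclude_border=False)
        assert kept.n_objects == 1
        assert all_objs.n_objects == 2

    def test_holes_are_filled(self):
        img = np.full((64, 64), 5.0)
        d = disc_mask((64, 64), (32, 32), 12)
        img[d] = 150.0
        img[30:34, 30:34] = 5.0  # intranuclear dark hole
        cm = segment_nuclei(make_dna(img), min_area_px=10, exclude_border=False)
        assert cm.n_objects == 1
        assert cm.labels[32, 32] == 1

    def test_raster_order_labels(self):
        img = np.full((64, 64), 5.0)
        img[disc_mask((64, 64), (45, 10), 6)] = 150.0
        img[disc_mask((64, 64), (10, 45), 6)] = 150.0
        cm = segment_nuclei(make_dna(img), min_area_px=10, exclude_border=False)
        assert cm.labels[10, 45] == 1  # first in raster order
        assert cm.labels[45, 10] == 2

    def test_requires_dna_role(self, three_disc_scene):
        img = make_damage(three_disc_scene.pixels)
        with pytest.raises(ValueError, match="role"):
            segment_nuclei(img)


class TestRollingBallSubtract:
    def test_constant_image_goes_to_zero(self):
        out = rolling_ball_subtract(make_dna(np.full((64, 64), 37.0)), radius_px=10)
        assert np.allclose(out.pixels, 0.0, atol=1e-9)

    def test_spike_preserved_vs_opening_oracle(self):
        img = np.zeros((64, 64))
        img[30, 30] = 100.0
        out = rolling_ball_subtract(make_dna(img), radius_px=10)
        assert out.pixels[30, 30] >= 90.0
        oracle_bg = opening(img, disk(10))
        oracle = np.clip(img - oracle_bg, 0, None)
        assert abs(out.pixels[30, 30] - oracle[30, 30]) <= 10.0

    def test_offset_invariance(self):
        img = np.zeros((64, 64))
        img[20, 40] = 80.0
        a = rolling_ball_subtract(make_dna(img), radius_px=10).pixels
        b = rolling_ball_subtract(make_dna(img + 25.0), radius_px=10).pixels
        assert np.max(np.abs(a - b)) <= 1.0

    def test_wide_plateau_removed(self):
        img = np.zeros((96, 96))
        img[20:80, 20:80] = 50.0  # extent >> radius
        out = rolling_ball_subtract(make_dna(img), radius_px=5)
        assert out.pixels[48, 48] <= 1.0

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=15, deadline=None)
    def test_bounded_between_zero_and_input(self, seed):
        img = np.random.default_rng(seed).uniform(0, 100, (48, 48))
        out = rolling_ball_subtract(make_dna(img), radius_px=5).pixels
        assert (out >= 0).all()
        assert (out <= img + 1e-9).all()

    def test_radius_too_large_raises(self):
        with pytest.raises(ValueError, match="radius too large"):
            rolling_ball_subtract(make_dna(np.zeros((32, 32)) + np.eye(32)), radius_px=32)


class TestDamageMask:
    def test_all_below_threshold(self):
        m = damage_mask(make_damage(np.full((16, 16), 3.0)), threshold=10.0)
        assert not m.mask.any()

    def test_strict_inequality_at_threshold(self):
        m = damage_mask(make_damage(np.full((16, 16), 10.0)), threshold=10.0)
        assert not m.mask.any()

    def test_two_foci_two_components(self):
        img = np.full((64, 64), 5.0)
        img[disc_mask((64, 64), (16, 16), 4)] = 100.0
        img[disc_mask((64, 64), (48, 48), 4)] = 100.0
        m = damage_mask(make_damage(img), threshold=50.0)
        labels, n = flood_fill_labels(m.mask)
        assert n == 2

    @given(t1=st.floats(0, 200), t2=st.floats(0, 200), seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_threshold(self, t1, t2, seed):
        lo, hi = sorted((t1, t2))
        img = make_damage(np.random.default_rng(seed).uniform(0, 200, (24, 24)))
        m_hi = damage_mask(img, hi).mask
        m_lo = damage_mask(img, lo).mask
        assert not (m_hi & ~m_lo).any()  # mask(t2) subset of mask(t1)

    def test_requires_damage_role(self):
        with pytest.raises(ValueError, match="role"):
            damage_mask(make_dna(np.ones((8, 8))), 0.5)


class TestCountFoci:
    def test_empty_damage_mask(self):
        assert count_foci(BinaryMask(np.zeros((32, 32), bool)), np.ones((32, 32), bool)) == 0

    def test_foci_outside_nucleus_ignored(self):
        dmg = np.zeros((64, 64), bool)
        for c in [(10, 10), (10, 30), (30, 10), (55, 55)]:  # last one outside
            dmg[disc_mask((64, 64), c, 2)] = True
        nucleus = disc_mask((64, 64), (20, 20), 18)
        assert count_foci(BinaryMask(dmg), nucleus, min_focus_px=1) == 3

    def test_min_focus_px_filter(self):
        dmg = np.zeros((32, 32), bool)
        dmg[5, 5] = True  # 1-px speck
        dmg[disc_mask((32, 32), (20, 20), 3)] = True
        nucleus = np.ones((32, 32), bool)
        assert count_foci(BinaryMask(dmg), nucleus, min_focus_px=2) == 1
        assert count_foci(BinaryMask(dmg), nucleus, min_focus_px=1) == 2

    def test_additive_over_disjoint_regions(self):
        rng = np.random.default_rng(5)
        dmg = BinaryMask(rng.uniform(size=(48, 48)) > 0.92)
        left = np.zeros((48, 48), bool)
        left[:, :24] = True
        right = ~left
        whole = count_foci(dmg, np.ones((48, 48), bool))
        # split along a column that crosses no focus to keep regions disjoint
        col_has_focus = dmg.mask[:, 23] | dmg.mask[:, 24]
        if not col_has_focus.any():
            assert count_foci(dmg, left) + count_foci(dmg, right) == whole

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            count_foci(BinaryMask(np.zeros((8, 8), bool)), np.ones((9, 9), bool))


class TestCountMaskType:
    def test_rejects_noncontiguous_labels(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[0, 0] = 2
        with pytest.raises(ValueError):
            CountMask(labels)

    def test_region_lookup(self, three_disc_scene):
        cm = segment_nuclei(three_disc_scene, min_area_px=50)
        assert cm.region(1).sum() > 0
        with pytest.raises(KeyError):
            cm.region(cm.n_objects + 1)
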