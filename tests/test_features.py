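import math

import numpy as np
import pytest

import vastree as vt
from vastree.errors import VastreeError
from vastree.features import segment_direction
from vastree.model import RIGHT_ANGLE


def bar_scene(width, length=60, angle_deg=0.0, size=160):
    """Straight tube of the given rendered width; returns (segment, mask)."""
    from skimage.draw import line

    from vastree.synthetic import _paint_tube

    mask = np.zeros((size, size), dtype=bool)
    c = np.array([size / 2.0, size / 2.0])
    phi = math.radians(angle_deg)
    u = np.array([-math.cos(phi), math.sin(phi)])
    a, b = c - length / 2 * u, c + length / 2 * u
    _paint_tube(mask, a, b, width / 2.0)
    ai, bi = np.rint(a).astype(int), np.rint(b).astype(int)
    rr, cc = line(ai[0], ai[1], bi[0], bi[1])
    seg = vt.VesselSegment("bar", path=np.stack([rr, cc], axis=1))
    return seg, mask


class TestSegmentAvgWidth:
    def test_five_px_bar(self):
        seg, mask = bar_scene(5.0)
        assert 4.0 <= vt.segment_avg_width(seg, mask) <= 6.0

    def test_one_px_line(self):
        seg, mask = bar_scene(1.0)
        assert 1.0 <= vt.segment_avg_width(seg, mask) <= 2.0

    def test_invariant_under_90_degree_rotation(self):
        seg_h, mask_h = bar_scene(5.0, angle_deg=90.0)
        seg_v, mask_v = bar_scene(5.0, angle_deg=0.0)
        w_h = vt.segment_avg_width(seg_h, mask_h)
        w_v = vt.segment_avg_width(seg_v, mask_v)
        assert abs(w_h - w_v) <= 0.1

    @pytest.mark.parametrize("width", [2.5, 4.5, 8.0])
    @pytest.mark.parametrize("angle", [2.5, 37.5, 62.5])
    def test_subpixel_accuracy(self, width, angle):
        seg, mask = bar_scene(width, angle_deg=angle)
        assert abs(vt.segment_avg_width(seg, mask) - width) <= 0.25

    def test_path_outside_mask_raises(self):
        seg, mask = bar_scene(5.0)
        mask[:] = False
        with pytest.raises(VastreeError, match="outside"):
            vt.segment_avg_width(seg, mask)


class TestLwRatio:
    def test_arithmetic(self):
        seg = vt.VesselSegment("s", length_px=100.0, avg_width_px=4.0)
        assert vt.lw_ratio(seg) == 25.0

    def test_unity(self):
        seg = vt.VesselSegment("s", length_px=4.0, avg_width_px=4.0)
        assert vt.lw_ratio(seg) == 1.0

    def test_zero_width_raises(self):
        seg = vt.VesselSegment("s", length_px=10.0, avg_width_px=0.0)
        with pytest.raises(VastreeError):
            vt.lw_ratio(seg)

    def test_scale_invariance_on_rendered_bars(self):
        # Doubling both length and rendered width leaves L/W unchanged
        # within 5%.
        seg1, mask1 = bar_scene(4.0, length=50, angle_deg=27.5)
        seg2, mask2 = bar_scene(8.0, length=100, angle_deg=27.5, size=240)
        r1 = seg1.length_px / vt.segment_avg_width(seg1, mask1)
        r2 = seg2.length_px / vt.segment_avg_width(seg2, mask2)
        assert abs(r1 - r2) / max(r1, r2) <= 0.05


class TestEncodeLandmark:
    def test_codes(self):
        assert vt.encode_landmark(vt.Landmark((0, 0), "bifurcation")) == 1
        assert vt.encode_landmark(vt.Landmark((0, 0), "branch")) == 0

    def test_crossover_rejected(self):
        with pytest.raises(VastreeError):
            vt.encode_landmark(vt.Landmark((0, 0), "crossover"))

    def test_all_truth_landmarks(self, truth):
        for lm in truth.landmarks:
            if lm.klass == "crossover":
                continue
            assert vt.encode_landmark(lm) == (1 if lm.klass == "bifurcation" else 0)


class TestCrossoverFeatures:
    def make_segment(self, n, cross_at=None):
        path = np.stack([np.full(n, 5), np.arange(n)], axis=1)
        seg = vt.VesselSegment("s", path=path)
        if cross_at is not None:
            lm = vt.Landmark((5, cross_at), "crossover")
            seg.crossovers_on_path = [(lm, cross_at)]
        return seg

    def test_worked_example_100_70(self):
        flag, pos = vt.crossover_features(self.make_segment(100, 70))
        assert flag == 1
        assert pos == 0.7

    def test_absent(self):
        assert vt.crossover_features(self.make_segment(100)) == (0, 0.0)

    def test_at_start(self):
        flag, pos = vt.crossover_features(self.make_segment(100, 0))
        assert (flag, pos) == (1, 0.0)

    def test_first_of_several(self):
        seg = self.make_segment(100)
        seg.crossovers_on_path = [
            (vt.Landmark((5, 80), "crossover"), 80),
            (vt.Landmark((5, 30), "crossover"), 30),
        ]
        assert vt.crossover_features(seg) == (1, 0.3)


def straight_segment(direction, n=40, start=(50.0, 50.0), width=1.0):
    t = np.arange(n, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pts = np.rint(np.array(start) + t[:, None] * d[None, :]).astype(int)
    seg = vt.VesselSegment("s", path=pts, avg_width_px=width)
    return seg


class TestAcuteAngle:
    def test_orthogonal(self):
        parent = straight_segment((0, 1), width=5.0)
        daughter = straight_segment((1, 0), start=(50, 90), width=2.0)
        assert vt.acute_angle(parent, [daughter]) == pytest.approx(
            RIGHT_ANGLE, abs=0.02
        )

    def test_parallel(self):
        parent = straight_segment((0, 1), width=5.0)
        daughter = straight_segment((0, 1), start=(50, 90), width=2.0)
        assert vt.acute_angle(parent, [daughter]) == pytest.approx(0.0, abs=0.02)

    def test_width_sort_picks_widest_and_narrowest(self):
        # parent width 5; daughters 3 (at 45 deg) and 2 (at 90 deg): the
        # 45-deg daughter is ignored.
        parent = straight_segment((0, 1), width=5.0)
        d_mid = straight_segment((1, 1), start=(50, 90), width=3.0)
        d_narrow = straight_segment((1, 0), start=(50, 90), width=2.0)
        angle = vt.acute_angle(parent, [d_mid, d_narrow])
        assert angle == pytest.approx(RIGHT_ANGLE, abs=0.02)

    def test_requires_daughters(self):
        with pytest.raises(VastreeError):
            vt.acute_angle(straight_segment((0, 1)), [])


class TestSegmentDirection:
    def test_short_segment_fallback(self):
        seg = vt.VesselSegment("s", path=np.array([[0, 0], [1, 1]]))
        d = segment_direction(seg, at_end=True)
        assert d == pytest.approx([1 / math.sqrt(2), 1 / math.sqrt(2)])

    def test_orientation_follows_walk(self):
        seg = straight_segment((0, 1))
        d_end = segment_direction(seg, at_end=True)
        d_start = segment_direction(seg, at_end=False)
        assert d_end @ np.array([0, 1]) > 0.99
        assert d_start @ np.array([0, 1]) > 0.99


class TestBuildFeatureVector:
    def test_terminal_node_shape(self, model):
        leaves = [
            n for t in model.trees for n in t.root.walk() if not n.children
        ]
        for leaf in leaves:
            f = leaf.features
            assert f.bibr_code == 0
            assert f.acute_angle == 0.0
            assert f.lw_ratio > 0

    def test_internal_nodes_have_angles(self, model):
        internal = [
            n for t in model.trees for n in t.root.walk() if n.children
        ]
        assert internal
        for node in internal:
            assert 0 < node.features.acute_angle < RIGHT_ANGLE

    def test_feature_ranges(self, model):
        for t in model.trees:
            for n in t.root.walk():
                f = n.features
                assert f.bibr_code in (0, 1)
                assert f.crossover_flag in (0, 1)
                assert 0.0 <= f.crossover_pos < 1.0
                assert 0.0 <= f.acute_angle <= RIGHT_ANGLE

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            vt.FeatureVector(1.0, 0, 0, 0.5, 0.0)  # pos without flag
        with pytest.raises(ValueError):
            vt.FeatureVector(1.0, 2, 0, 0.0, 0.0)


class TestNormalizeModel:
    def test_max_lw_becomes_one(self, model):
        norm, params = vt.normalize_model(model)
        lws = [n.features.lw_ratio for t in norm.trees for n in t.root.walk()]
        assert max(lws) == pytest.approx(1.0)
        assert params.lw_max == pytest.approx(
            max(n.features.lw_ratio for t in model.trees for n in t.root.walk())
        )

    def test_angle_scaling(self):
        from treeutil import make_model, make_tree

        model = make_model([make_tree(lw=10.0, bibr=1, angle=RIGHT_ANGLE)])
        norm, _ = vt.normalize_model(model)
        assert norm.trees[0].root.features.acute_angle == pytest.approx(1.0)

    def test_idempotent(self, model):
        norm1, p1 = vt.normalize_model(model)
        norm2, p2 = vt.normalize_model(norm1)
        assert norm2 is norm1
        assert p2 == p1

    def test_empty_model(self):
        norm, params = vt.normalize_model(vt.TreeModel(None, []))
        assert params.lw_max == 1.0
        assert norm.n_trees == 0

    def test_matching_unchanged_by_normalization(self, model, scene, truth):
        # Matching results are identical whether both models are raw or
        # both normalized, because the tolerances are scale-aware.
        scene_r, _ = vt.rotate_scene(scene, truth, 20.0)
        model_r = vt.build_tree_model(scene_r)
        raw = vt.vessel_distance_matrix(model, model_r)
        na, _ = vt.normalize_model(model)
        nb, _ = vt.normalize_model(model_r)
        normed = vt.vessel_distance_matrix(na, nb)
        assert np.array_equal(raw.values, normed.values)
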