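import numpy as np
import pytest

import vastree as vt
from vastree.errors import LandmarkSnapError, TraceError
from vastree.evaluate import model_matches_truth, pair_trees_to_truth
from vastree.tree_builder import BuildConfig, _Tracer


def blank(size=100):
    return np.zeros((size, size), dtype=bool)


def make_scene(cl, landmarks=(), od=None):
    mask = cl.copy()
    return vt.VascularScene(cl, mask, list(landmarks), od)


class TestFindVesselRoots:
    def test_synthetic_roots_match_truth(self, scene, truth):
        roots = vt.find_vessel_roots(scene)
        assert len(roots) == len(truth.vessels)
        starts = np.array([v.start for v in truth.vessels])
        for rp in roots:
            d = np.linalg.norm(starts - np.array(rp, dtype=float), axis=1)
            assert d.min() <= 3.0

    def test_blank_raster(self):
        scene = make_scene(blank(), od=vt.OpticDiscSpec((50.0, 50.0), 10.0))
        assert vt.find_vessel_roots(scene) == []

    def test_adjacent_hits_cluster_to_one_root(self):
        cl = blank()
        cl[50, 60:75] = True  # crosses the annulus [10, 13] over several px
        scene = make_scene(cl, od=vt.OpticDiscSpec((50.0, 50.0), 10.0))
        roots = vt.find_vessel_roots(scene)
        assert len(roots) == 1

    def test_clockwise_order_from_12_oclock(self):
        cl = blank()
        od = vt.OpticDiscSpec((50.0, 50.0), 10.0)
        cl[28:39, 50] = True  # 12 o'clock (up)
        cl[50, 61:72] = True  # 3 o'clock (right)
        cl[61:72, 50] = True  # 6 o'clock (down)
        scene = make_scene(cl, od=od)
        roots = vt.find_vessel_roots(scene)
        assert len(roots) == 3
        assert roots[0][0] < 50  # up first
        assert roots[1][1] > 50  # then right
        assert roots[2][0] > 50  # then down


class TestFragmentCenterline:
    def test_straight_line_with_bifurcation(self):
        cl = blank()
        cl[50, 10:60] = True
        # two outgoing arms from the landmark at (50, 35)
        for k in range(1, 20):
            cl[50 - k, 35 + k] = True
        lm = vt.Landmark((50, 35), "bifurcation")
        frag = vt.fragment_centerline(make_scene(cl, [lm]))
        assert frag.n_fragments == 3

    def test_no_landmarks_one_fragment_per_component(self):
        cl = blank()
        cl[20, 10:40] = True
        cl[60, 10:40] = True
        frag = vt.fragment_centerline(make_scene(cl))
        assert frag.n_fragments == 2

    def test_x_crossing_gives_four_fragments(self):
        cl = blank()
        cl[50, 20:81] = True
        cl[20:81, 50] = True
        lm = vt.Landmark((50, 50), "crossover")
        frag = vt.fragment_centerline(make_scene(cl, [lm]))
        assert frag.n_fragments == 4

    def test_landmark_snapping_and_error(self):
        cl = blank()
        cl[50, 10:60] = True
        # 2 px off: snaps (with a warning) to the nearest centerline pixel
        frag = vt.fragment_centerline(
            make_scene(cl, [vt.Landmark((52, 30), "branch")])
        )
        assert frag.landmarks[0].position == (50, 30)
        with pytest.raises(LandmarkSnapError):
            vt.fragment_centerline(
                make_scene(cl, [vt.Landmark((80, 80), "branch")])
            )


class TestTraceSegment:
    def test_horizontal_line(self):
        cl = blank()
        cl[50, 10:20] = True
        frag = vt.fragment_centerline(make_scene(cl))
        seg = vt.trace_segment(frag, (50, 10), (0.0, 1.0))
        assert seg.n_pixels == 10
        assert seg.end == (50, 19)
        assert seg.terminating_landmark is None

    def test_l_shaped_path_via_8_connectivity(self):
        # 6 px right then 5 px down with a diagonal corner: one 10-px walk.
        cl = blank()
        cl[50, 10:16] = True
        for k in range(1, 5):
            cl[51 + k, 16 + 0] = True
        cl[51, 16] = True  # diagonal corner pixel
        frag = vt.fragment_centerline(make_scene(cl))
        seg = vt.trace_segment(frag, (50, 10), (0.0, 1.0))
        assert seg.n_pixels == 11
        assert seg.end == (55, 16)

    def test_terminates_at_bifurcation(self):
        cl = blank()
        cl[50, 10:40] = True
        for k in range(1, 15):
            cl[50 - k, 40 + k] = True
            cl[50 + k, 40 + k] = True
        cl[50, 40] = True
        lm = vt.Landmark((50, 40), "bifurcation")
        frag = vt.fragment_centerline(make_scene(cl, [lm]))
        seg = vt.trace_segment(frag, (50, 10), (0.0, 1.0))
        assert seg.terminating_landmark is not None
        assert seg.terminating_landmark.klass == "bifurcation"

    def test_invalid_start_pixel(self):
        cl = blank()
        cl[50, 10:20] = True
        frag = vt.fragment_centerline(make_scene(cl))
        with pytest.raises(TraceError):
            vt.trace_segment(frag, (5, 5))

    def test_covers_whole_fragment_from_mid_start(self):
        cl = blank()
        cl[50, 10:40] = True
        frag = vt.fragment_centerline(make_scene(cl))
        seg = vt.trace_segment(frag, (50, 25), (0.0, 1.0))
        assert seg.n_pixels == 30


class TestCrossoverContinuation:
    def cross_scene(self):
        cl = blank()
        cl[50, 10:91] = True
        cl[10:91, 50] = True
        lm = vt.Landmark((50, 50), "crossover")
        return make_scene(cl, [lm])

    def test_straight_through_with_midpoint_index(self):
        frag = vt.fragment_centerline(self.cross_scene())
        seg = vt.trace_segment(frag, (50, 10), (0.0, 1.0))
        assert seg.n_pixels == 81  # both parts joined across the crossing
        assert seg.end == (50, 90)
        assert len(seg.crossovers_on_path) == 1
        _, idx = seg.crossovers_on_path[0]
        assert abs(idx - 40) <= 2  # ~ path midpoint

    def test_minimal_deviation_picks_straight_arm(self):
        frag = vt.fragment_centerline(self.cross_scene())
        tracer = _Tracer(frag, BuildConfig())
        seg = tracer.trace_segment((50, 10), (0.0, 1.0))
        # continuation went straight: end on the horizontal line
        assert seg.end[0] == 50

    def test_both_vessels_fully_traced(self):
        frag = vt.fragment_centerline(self.cross_scene())
        tracer = _Tracer(frag, BuildConfig())
        s1 = tracer.trace_segment((50, 10), (0.0, 1.0))
        s2 = tracer.trace_segment((10, 50), (1.0, 0.0))
        assert s1.end == (50, 90)
        assert s2.end == (90, 50)
        assert len(s2.crossovers_on_path) == 1


class TestBuildTreeModel:
    def test_five_vessel_scene_gives_five_trees(self, scene, model):
        assert model.n_trees == 5
        assert model.finalized

    def test_node_count_matches_truth(self, model, truth):
        assert model.n_nodes == truth.n_segments

    def test_topology_recovered(self, model, truth):
        assert model_matches_truth(model, truth)

    def test_empty_scene(self):
        scene = make_scene(blank(), od=vt.OpticDiscSpec((50.0, 50.0), 10.0))
        model = vt.build_tree_model(scene)
        assert model.n_trees == 0

    def test_single_vessel_no_landmarks(self):
        cl = blank(200)
        cl[100, 112:160] = True
        mask = np.zeros_like(cl)
        mask[98:103, 112:160] = True
        scene = vt.VascularScene(cl, mask, [], vt.OpticDiscSpec((100.0, 100.0), 10.0))
        model = vt.build_tree_model(scene)
        assert model.n_trees == 1
        assert model.trees[0].n_nodes == 1
        assert model.trees[0].root.segment.terminating_landmark is None

    def test_crossover_recorded_in_tree(self, model, truth):
        # Every truth segment with a crossover maps to a node whose flag is 1.
        mapping = pair_trees_to_truth(model, truth)
        for root in truth.vessels:
            tree = model.trees[mapping[root.vessel_id]]

            def pairs(node, ts):
                yield node, ts
                if ts.children:
                    yield from pairs(node.left_child, ts.children[0])
                    yield from pairs(node.right_child, ts.children[1])

            for node, ts in pairs(tree.root, root):
                assert node.features.crossover_flag == (1 if ts.crossovers else 0)

    def test_translation_invariance(self, default_spec):
        scene, truth = vt.generate_scene(default_spec)
        model_a = vt.build_tree_model(scene)
        # Shift the whole scene by (dr, dc) on a larger canvas (no wrap).
        dr, dc, pad = 7, 11, 20
        n = scene.shape[0]
        cl = np.zeros((n + 2 * pad, n + 2 * pad), dtype=bool)
        mask = np.zeros_like(cl)
        cl[pad + dr:pad + dr + n, pad + dc:pad + dc + n] = scene.centerline
        mask[pad + dr:pad + dr + n, pad + dc:pad + dc + n] = scene.vessel_mask
        off = pad
        lms = [
            vt.Landmark(
                (lm.position[0] + dr + off, lm.position[1] + dc + off), lm.klass
            )
            for lm in scene.landmarks
        ]
        od = vt.OpticDiscSpec(
            (scene.od.center[0] + dr + off, scene.od.center[1] + dc + off),
            scene.od.radius,
        )
        model_b = vt.build_tree_model(vt.VascularScene(cl, mask, lms, od))
        dr, dc = dr + off, dc + off  # total offset for the checks below
        assert model_b.n_trees == model_a.n_trees
        for ta, tb in zip(model_a.trees, model_b.trees):
            for na, nb in zip(ta.root.walk(), tb.root.walk()):
                fa, fb = na.features, nb.features
                assert (fa.bibr_code, fa.crossover_flag) == (
                    fb.bibr_code, fb.crossover_flag,
                )
                assert fa.lw_ratio == pytest.approx(fb.lw_ratio, rel=1e-9)
                assert fa.crossover_pos == pytest.approx(fb.crossover_pos)
                assert fa.acute_angle == pytest.approx(fb.acute_angle, abs=1e-9)
                assert nb.segment.start == (
                    na.segment.start[0] + dr, na.segment.start[1] + dc,
                )

    def test_visited_flags_partition_segments(self, model, scene):
        # No fragment pixel belongs to two traced segments.  (Crossover-zone
        # pixels are bridged by both crossing vessels and are exempt.)
        frag = vt.fragment_centerline(scene)
        seen = set()
        for tree in model.trees:
            for node in tree.root.walk():
                for p in map(tuple, node.segment.path):
                    if frag.boundary[p]:
                        continue
                    assert p not in seen
                    seen.add(p)
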