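"""Ground-truth comparison helpers and the rotation-robustness harness.

These utilities link rebuilt tree models back to the generator's ground
truth (vessel identity survives rotation through the root positions) and
drive the rotate -> rebuild -> compare experiment that demonstrates the
rotation invariance of the matching under the +/-5% tolerance.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .matching import MatchConfig, find_correspondence, tree_distance
from .model import BinaryVesselTree, SegmentNode, TreeModel
from .synthetic import GroundTruthTopology, TruthSegment, rotate_scene
from .scene import VascularScene
from .tree_builder import BuildConfig, build_tree_model


def pair_trees_to_truth(
    model: TreeModel, truth: GroundTruthTopology, max_offset: float = 6.0
) -> dict[str, int]:
    """Map ground-truth vessel ids to tree indices in ``model``.

    Built root segments are oriented outward from the optic disc, so the
    first path pixel of each root lies near the ground-truth root start;
    vessels are paired by nearest root start.
    """
    out: dict[str, int] = {}
    taken: set[int] = set()
    for root in truth.vessels:
        best, best_d = None, np.inf
        for i, tree in enumerate(model.trees):
            if i in taken:
                continue
            p = np.asarray(tree.root.segment.path[0], dtype=float)
            d = float(np.linalg.norm(p - root.start))
            if d < best_d:
                best, best_d = i, d
        if best is None or best_d > max_offset:
            raise ValueError(
                f"no built tree found near ground-truth vessel "
                f"{root.vessel_id} (closest at {best_d:.1f} px)"
            )
        out[root.vessel_id] = best
        taken.add(best)
    return out


def tree_matches_truth(
    tree: BinaryVesselTree, truth_root: TruthSegment, position_tol: float = 4.0
) -> bool:
    """True if a built tree is isomorphic to its ground-truth tree.

    Checked recursively: same child structure, same terminating landmark
    class at (approximately) the same position, children aligned by the
    width order (ground truth puts the wide daughter first; the builder
    puts the wider measured daughter left).
    """

    def rec(node: SegmentNode | None, ts: TruthSegment | None) -> bool:
        if node is None or ts is None:
            return node is None and ts is None
        built_children = [node.left_child, node.right_child]
        built_children = [c for c in built_children if c is not None]
        if len(built_children) != len(ts.children):
            return False
        if ts.children:
            lm = node.segment.terminating_landmark
            if lm is None or lm.klass != ts.terminal_class:
                return False
            jp = np.asarray(lm.position, dtype=float)
            if float(np.linalg.norm(jp - ts.end)) > position_tol:
                return False
            return rec(node.left_child, ts.children[0]) and rec(
                node.right_child, ts.children[1]
            )
        return node.segment.terminating_landmark is None or (
            node.segment.terminating_landmark.klass == "crossover"
        )

    return rec(tree.root, truth_root)


def model_matches_truth(model: TreeModel, truth: GroundTruthTopology) -> bool:
    """Topology recovery over the whole scene: every vessel's built tree is
    isomorphic to its ground-truth tree."""
    if model.n_trees != len(truth.vessels):
        return False
    mapping = pair_trees_to_truth(model, truth)
    return all(
        tree_matches_truth(model.trees[mapping[root.vessel_id]], root)
        for root in truth.vessels
    )


DEFAULT_ANGLES = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


def rotation_eval(
    scene: VascularScene,
    truth: GroundTruthTopology,
    angles=DEFAULT_ANGLES,
    cfg: MatchConfig = MatchConfig(),
    build_config: BuildConfig = BuildConfig(),
) -> pd.DataFrame:
    """Rotate, rebuild and compare: one row per (angle, vessel).

    Columns: ``angle``, ``vessel``, ``distance_tolerance_on`` (matching with
    the configured tolerances), ``distance_tolerance_off`` (exact feature
    equality), and the min/max distance of the vessel against the *other*
    vessels of the rotated model with tolerance on.
    """
    cfg_off = replace(cfg, rel_tolerance=0.0, angle_tolerance=0.0)
    model0 = build_tree_model(scene, build_config)
    map0 = pair_trees_to_truth(model0, truth)
    rows = []
    for angle in angles:
        scene_r, truth_r = rotate_scene(scene, truth, float(angle))
        model_r = build_tree_model(scene_r, build_config)
        map_r = pair_trees_to_truth(model_r, truth_r)
        for root in truth.vessels:
            vid = root.vessel_id
            t0 = model0.trees[map0[vid]]
            tr = model_r.trees[map_r[vid]]
            d_on = tree_distance(t0, tr, cfg)
            d_off = tree_distance(t0, tr, cfg_off)
            cross = [
                tree_distance(t0, model_r.trees[map_r[other.vessel_id]], cfg)
                for other in truth.vessels
                if other.vessel_id != vid
            ]
            rows.append(
                {
                    "angle": float(angle),
                    "vessel": vid,
                    "distance_tolerance_on": d_on,
                    "distance_tolerance_off": d_off,
                    "min_cross_distance": min(cross) if cross else math.nan,
                    "max_cross_distance": max(cross) if cross else math.nan,
                }
            )
    return pd.DataFrame(rows)


def correspondence_recovers_truth(
    scene: VascularScene,
    truth: GroundTruthTopology,
    angle: float,
    cfg: MatchConfig = MatchConfig(),
    build_config: BuildConfig = BuildConfig(),
) -> bool:
    """True if greedy matching pairs each vessel of the original model with
    the ground-truth same vessel of the rotated rebuild."""
    model0 = build_tree_model(scene, build_config)
    scene_r, truth_r = rotate_scene(scene, truth, angle)
    model_r = build_tree_model(scene_r, build_config)
    map0 = pair_trees_to_truth(model0, truth)
    map_r = pair_trees_to_truth(model_r, truth_r)
    want = {map0[v.vessel_id]: map_r[v.vessel_id] for v in truth.vessels}
    corr = find_correspondence(model0, model_r, cfg)
    return all(want.get(i) == j for i, j, _ in corr.pairs)
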