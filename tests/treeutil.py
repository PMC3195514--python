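"""Hand-built and random feature trees for matcher tests, plus an
independent brute-force distance oracle."""

from __future__ import annotations

import numpy as np

from vastree import (
    BinaryVesselTree,
    FeatureVector,
    MatchConfig,
    OpticDiscSpec,
    SegmentNode,
    TreeModel,
)


def make_node(lw=10.0, bibr=0, flag=0, pos=0.0, angle=0.0,
              left=None, right=None, level=0):
    return SegmentNode(
        segment=None,
        features=FeatureVector(lw, bibr, flag, pos, angle),
        left_child=left,
        right_child=right,
        level=level,
    )


def make_tree(vessel_id="v0", **kwargs):
    return BinaryVesselTree(vessel_id, make_node(**kwargs))


def complete_tree(vessel_id, depth, feature_fn):
    """Complete binary tree; feature_fn(level, index_in_level) -> kwargs."""

    def build(level, idx):
        node = make_node(level=level, **feature_fn(level, idx))
        if level < depth:
            node.left_child = build(level + 1, 2 * idx)
            node.right_child = build(level + 1, 2 * idx + 1)
        return node

    return BinaryVesselTree(vessel_id, build(0, 0))


def make_model(trees, od=None):
    od = od or OpticDiscSpec((50.0, 50.0), 10.0)
    return TreeModel(od, list(trees))


# A coarse value grid makes near-ties (within 5% tolerance) common, so the
# tolerance path of the matcher is genuinely exercised by random trees.
_LW_GRID = [5.0, 5.2, 10.0, 10.4, 40.0, 41.0, 80.0]
_POS_GRID = [0.0, 0.3, 0.32, 0.7, 0.72]
_ANGLE_GRID = [0.0, 0.05, 0.5, 0.52, 1.2]


def random_tree(rng: np.random.Generator, depth=2, p_child=0.7, vessel_id="r"):
    def build(level):
        node = make_node(
            lw=float(rng.choice(_LW_GRID)),
            bibr=int(rng.integers(0, 2)),
            flag=int(rng.integers(0, 2)),
            angle=float(rng.choice(_ANGLE_GRID)),
            level=level,
        )
        if node.features.crossover_flag:
            pos = float(rng.choice(_POS_GRID[1:]))
            node.features = FeatureVector(
                node.features.lw_ratio, node.features.bibr_code, 1, pos,
                node.features.acute_angle,
            )
        if level < depth and rng.random() < p_child:
            node.left_child = build(level + 1)
        if level < depth and rng.random() < p_child:
            node.right_child = build(level + 1)
        return node

    return BinaryVesselTree(vessel_id, build(0))


def brute_force_distance(t1, t2, cfg: MatchConfig, depth: int) -> int:
    """Array-based mismatch counter, independent of the preorder machinery.

    Materializes both trees into complete-tree arrays indexed by the heap
    rule (children of i at 2i+1, 2i+2) and compares position by position
    with a from-scratch feature comparison.
    """
    n = 2 ** (depth + 1) - 1

    def fill(node, idx, arr):
        if node is None or idx >= n:
            return
        arr[idx] = node.features
        fill(node.left_child, 2 * idx + 1, arr)
        fill(node.right_child, 2 * idx + 2, arr)

    a = [None] * n
    b = [None] * n
    fill(t1.root if hasattr(t1, "root") else t1, 0, a)
    fill(t2.root if hasattr(t2, "root") else t2, 0, b)
    dist = 0
    for fa, fb in zip(a, b):
        if fa is None and fb is None:
            continue
        if fa is None or fb is None:
            dist += 1
            continue
        ok = (
            fa.bibr_code == fb.bibr_code
            and fa.crossover_flag == fb.crossover_flag
            and abs(fa.lw_ratio - fb.lw_ratio)
            <= cfg.rel_tolerance * max(fa.lw_ratio, fb.lw_ratio, cfg.eps)
            and abs(fa.crossover_pos - fb.crossover_pos) <= cfg.rel_tolerance
            and abs(fa.acute_angle - fb.acute_angle) <= cfg.angle_tolerance
        )
        if not ok:
            dist += 1
    return dist
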