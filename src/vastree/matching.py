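"""Tree-model comparison: preorder alignment, tolerance matching and
node-count distances.

Two binary vessel trees are compared position-by-position along the
preorder traversal of the *complete* binary tree of a fixed depth, absent
positions being explicit gaps.  A node pair matches when the discrete
features (bifurcation/branch code, crossover flag) are equal and the
continuous features (L/W, crossover position, acute angle) agree within
tolerance; the distance between two trees is the number of non-matching
positions.  Vessel correspondence between two models is found greedily by
minimum distance over the upper levels of the trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ModelFormatError
from .model import RIGHT_ANGLE, BinaryVesselTree, FeatureVector, SegmentNode, TreeModel


@dataclass(frozen=True)
class MatchConfig:
    """Matching tolerances and candidate-search depth.

    ``rel_tolerance`` applies relatively to L/W and absolutely to the
    crossover position (itself already a ratio in [0, 1]).
    ``angle_tolerance`` is in radians; the default is 5% of a right angle.
    Setting it to 0 makes the angle comparison exact.  ``candidate_depth``
    is the deepest level compared (0..2 covers up to 7 nodes).
    """

    rel_tolerance: float = 0.05
    angle_tolerance: float = 0.05 * RIGHT_ANGLE
    candidate_depth: int = 2
    eps: float = 1e-9

    def __post_init__(self) -> None:
        if self.rel_tolerance < 0 or self.angle_tolerance < 0:
            raise ValueError("tolerances must be >= 0")
        if self.candidate_depth < 0:
            raise ValueError("candidate_depth must be >= 0")

    @property
    def n_positions(self) -> int:
        """Node count of the complete binary tree at candidate_depth."""
        return 2 ** (self.candidate_depth + 1) - 1


@dataclass
class DistanceMatrix:
    """Labelled integer matrix of node-count distances."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ModelFormatError(
                f"matrix shape {self.values.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})"
            )

    @property
    def is_square(self) -> bool:
        return self.values.shape[0] == self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ModelCorrespondence:
    """Greedy vessel pairing between two tree models."""

    pairs: list[tuple[int, int, int]] = field(default_factory=list)
    unmatched_a: list[int] = field(default_factory=list)
    unmatched_b: list[int] = field(default_factory=list)

    @property
    def total_distance(self) -> int:
        return sum(d for _, _, d in self.pairs)

    def to_json_dict(self, model_a: TreeModel | None = None,
                     model_b: TreeModel | None = None) -> dict:
        def lab(model, i):
            return model.trees[i].vessel_id if model is not None else i

        return {
            "pairs": [
                {"a": lab(model_a, i), "b": lab(model_b, j), "distance": int(d)}
                for i, j, d in self.pairs
            ],
            "unmatched": {
                "a": [lab(model_a, i) for i in self.unmatched_a],
                "b": [lab(model_b, j) for j in self.unmatched_b],
            },
            "total_distance": int(self.total_distance),
        }


def preorder_nodes(
    tree: BinaryVesselTree | SegmentNode, depth_limit: int | None = None
) -> list[SegmentNode | None]:
    """Preorder sequence over the complete binary tree of ``depth_limit``
    levels, with ``None`` gaps for absent positions.

    With no depth limit, the sequence covers the complete tree of the same
    depth as the input tree (so two trees of different shape still align
    position-by-position when given the same limit).
    """
    root = tree.root if isinstance(tree, BinaryVesselTree) else tree

    def depth_of(node: SegmentNode | None) -> int:
        if node is None:
            return -1
        return 1 + max(depth_of(node.left_child), depth_of(node.right_child))

    limit = depth_limit if depth_limit is not None else depth_of(root)
    out: list[SegmentNode | None] = []

    def visit(node: SegmentNode | None, level: int) -> None:
        if level > limit:
            return
        out.append(node)
        visit(node.left_child if node is not None else None, level + 1)
        visit(node.right_child if node is not None else None, level + 1)

    visit(root, 0)
    return out


#: Identity feature scales (raw model): multipliers that bring a vector's
#: L/W and angle back to their unnormalized values.
RAW_SCALE = (1.0, 1.0)


def node_match(
    a: FeatureVector | None,
    b: FeatureVector | None,
    cfg: MatchConfig = MatchConfig(),
    scale_a: tuple[float, float] = RAW_SCALE,
    scale_b: tuple[float, float] = RAW_SCALE,
) -> bool:
    """Tolerance comparison of two feature vectors (or gaps).

    Both gaps match; a gap against a node does not.  Discrete features must
    be equal; L/W must agree within ``rel_tolerance`` relative to the larger
    of the two; the crossover position within ``rel_tolerance`` absolutely;
    the angle within ``angle_tolerance`` radians.  ``scale_a``/``scale_b``
    are per-model ``(lw, angle)`` multipliers that undo normalization, so
    matching normalized models gives the same result as matching raw ones.
    """
    if a is None and b is None:
        return True
    if a is None or b is None:
        return False
    if a.bibr_code != b.bibr_code or a.crossover_flag != b.crossover_flag:
        return False
    lw_a = a.lw_ratio * scale_a[0]
    lw_b = b.lw_ratio * scale_b[0]
    denom = max(lw_a, lw_b, cfg.eps)
    if abs(lw_a - lw_b) / denom > cfg.rel_tolerance:
        return False
    if abs(a.crossover_pos - b.crossover_pos) > cfg.rel_tolerance:
        return False
    angle_a = a.acute_angle * scale_a[1]
    angle_b = b.acute_angle * scale_b[1]
    if abs(angle_a - angle_b) > cfg.angle_tolerance:
        return False
    return True


def tree_distance(
    t1: BinaryVesselTree | SegmentNode,
    t2: BinaryVesselTree | SegmentNode,
    cfg: MatchConfig = MatchConfig(),
    depth_limit: int | None = None,
    scale_a: tuple[float, float] = RAW_SCALE,
    scale_b: tuple[float, float] = RAW_SCALE,
) -> int:
    """Number of preorder-aligned positions whose feature vectors differ."""
    limit = depth_limit if depth_limit is not None else cfg.candidate_depth
    seq1 = preorder_nodes(t1, limit)
    seq2 = preorder_nodes(t2, limit)
    dist = 0
    for n1, n2 in zip(seq1, seq2):
        f1 = n1.features if n1 is not None else None
        f2 = n2.features if n2 is not None else None
        if not node_match(f1, f2, cfg, scale_a=scale_a, scale_b=scale_b):
            dist += 1
    return dist


def _model_scales(
    model_a: TreeModel, model_b: TreeModel
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Per-model (lw, angle) de-normalization multipliers for matching."""
    if (model_a.normalization is None) != (model_b.normalization is None):
        raise ModelFormatError(
            "cannot match a normalized model against a raw one; "
            "normalize both or neither"
        )

    def scales(m: TreeModel) -> tuple[float, float]:
        if m.normalization is None:
            return RAW_SCALE
        return (m.normalization.lw_max, m.normalization.angle_scale)

    return scales(model_a), scales(model_b)


def find_correspondence(
    model_a: TreeModel, model_b: TreeModel, cfg: MatchConfig = MatchConfig()
) -> ModelCorrespondence:
    """Greedy vessel pairing: each tree of A takes the closest unmatched
    tree of B (ties to the lowest B index); pairing happens even when the
    best distance is nonzero, relying on the best match between trees."""
    scale_a, scale_b = _model_scales(model_a, model_b)
    out = ModelCorrespondence()
    free = list(range(model_b.n_trees))
    for i, ta in enumerate(model_a.trees):
        if not free:
            out.unmatched_a.append(i)
            continue
        dists = [
            (
                tree_distance(
                    ta, model_b.trees[j], cfg,
                    scale_a=scale_a, scale_b=scale_b,
                ),
                j,
            )
            for j in free
        ]
        d, j = min(dists)
        out.pairs.append((i, j, d))
        free.remove(j)
    out.unmatched_b = free
    return out


def vessel_distance_matrix(
    model_a: TreeModel, model_b: TreeModel, cfg: MatchConfig = MatchConfig()
) -> DistanceMatrix:
    """Full |A| x |B| matrix of tree distances at the candidate depth."""
    scale_a, scale_b = _model_scales(model_a, model_b)
    values = np.array(
        [
            [
                tree_distance(ta, tb, cfg, scale_a=scale_a, scale_b=scale_b)
                for tb in model_b.trees
            ]
            for ta in model_a.trees
        ],
        dtype=int,
    ).reshape(model_a.n_trees, model_b.n_trees)
    return DistanceMatrix(
        [t.vessel_id for t in model_a.trees],
        [t.vessel_id for t in model_b.trees],
        values,
    )


def model_distance_matrix(
    models: list[TreeModel],
    cfg: MatchConfig = MatchConfig(),
    labels: list[str] | None = None,
) -> DistanceMatrix:
    """Inter-model distance matrix: entry (i, j) sums the greedy pair
    distances plus a full-tree penalty per unmatched vessel.

    Computed for i < j and mirrored, so the matrix is symmetric by
    construction; the diagonal is zero.
    """
    if not models:
        raise ModelFormatError("model_distance_matrix requires at least one model")
    n = len(models)
    if labels is None:
        labels = [f"model_{i}" for i in range(n)]
    values = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            corr = find_correspondence(models[i], models[j], cfg)
            penalty = cfg.n_positions * (
                len(corr.unmatched_a) + len(corr.unmatched_b)
            )
            values[i, j] = values[j, i] = corr.total_distance + penalty
    return DistanceMatrix(list(labels), list(labels), values)
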