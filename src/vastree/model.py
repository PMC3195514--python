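"""Domain types for the hierarchical tree model.

The tree model represents a retinal vascular network as a root (the optic
disc) plus one binary tree per vessel.  Each node holds one traced vessel
segment together with its five rotation/translation/scale-invariant
features:

======================  =====================================================
feature                 meaning
======================  =====================================================
``lw_ratio``            segment length / average segment width (L/W)
``bibr_code``           1 if the segment ends at a bifurcation, 0 at a branch
                        (terminal segments also carry 0)
``crossover_flag``      1 if a crossover lies on the segment, else 0
``crossover_pos``       relative position of the first crossover along the
                        segment (pixel index / pixel count), 0 if none
``acute_angle``         acute angle (radians) between the widest and the
                        narrowest of {parent, daughters} at the terminating
                        landmark; 0 for terminal segments
======================  =====================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scene import Landmark, OpticDiscSpec

RIGHT_ANGLE = math.pi / 2.0


@dataclass
class VesselSegment:
    """An ordered centerline pixel run between landmarks (or tips).

    ``path`` is an ordered ``(n, 2)`` array of 8-adjacent ``(row, col)``
    pixels.  ``length_px`` is the Euclidean polyline length in pixel units
    (chord-resampled, so it is stable under raster rotation), while
    ``n_pixels`` is the raw pixel count used for the crossover-position
    ratio.
    """

    segment_id: str
    path: np.ndarray | None = None
    terminating_landmark: Landmark | None = None
    origin_landmark: Landmark | None = None
    crossovers_on_path: list[tuple[Landmark, int]] = field(default_factory=list)
    length_px: float = 0.0
    avg_width_px: float = 0.0
    n_pixels: int = 0
    start: tuple[int, int] | None = None
    end: tuple[int, int] | None = None
    #: Subpixel anchor points used for the length measurement: where the
    #: segment's centerline meets the originating / terminating junction.
    #: Defaults to the (rounded) landmark positions; the tree builder
    #: refines them to the least-squares intersection of the centerline
    #: directions meeting at the junction.
    origin_point: tuple[float, float] | None = None
    terminating_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.path is not None:
            self.path = np.asarray(self.path, dtype=int)
            if self.n_pixels == 0:
                self.n_pixels = len(self.path)
            if self.length_px == 0.0:
                self.length_px = polyline_length(self.path)
            self.sync_endpoints()

    def sync_endpoints(self) -> None:
        """Refresh ``start``/``end`` from the path (e.g. after reversal)."""
        if self.path is not None and len(self.path):
            self.start = (int(self.path[0][0]), int(self.path[0][1]))
            self.end = (int(self.path[-1][0]), int(self.path[-1][1]))


def polyline_length(path: np.ndarray, chord_step: int = 10) -> float:
    """Euclidean length of a pixel path, resampled with chords.

    Summing unit/diagonal steps of a digital line systematically over- or
    under-estimates its geometric length depending on orientation; chords
    spanning ``chord_step`` pixels remove almost all of that anisotropy,
    which is what makes the L/W feature stable under raster rotation.
    """
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        return 0.0
    idx = list(range(0, len(path) - 1, chord_step)) + [len(path) - 1]
    pts = path[idx]
    return float(np.sum(np.hypot(*(np.diff(pts, axis=0).T))))


@dataclass(frozen=True)
class FeatureVector:
    """The five invariant features of one tree-model node."""

    lw_ratio: float
    bibr_code: int
    crossover_flag: int
    crossover_pos: float
    acute_angle: float

    def __post_init__(self) -> None:
        if self.bibr_code not in (0, 1):
            raise ValueError(f"bibr_code must be 0 or 1, got {self.bibr_code}")
        if self.crossover_flag not in (0, 1):
            raise ValueError(
                f"crossover_flag must be 0 or 1, got {self.crossover_flag}"
            )
        if self.crossover_flag == 0 and self.crossover_pos != 0:
            raise ValueError("crossover_pos must be 0 when crossover_flag is 0")

    def as_tuple(self) -> tuple[float, int, int, float, float]:
        """Values in serialization column order: L/W, Bi/Br, Crossover,
        Cross pos., Acute angle."""
        return (
            self.lw_ratio,
            self.bibr_code,
            self.crossover_flag,
            self.crossover_pos,
            self.acute_angle,
        )


@dataclass
class SegmentNode:
    """A binary-tree node: one vessel segment plus its feature vector."""

    segment: VesselSegment | None = None
    features: FeatureVector | None = None
    left_child: "SegmentNode | None" = None
    right_child: "SegmentNode | None" = None
    level: int = 0

    @property
    def children(self) -> list["SegmentNode"]:
        return [c for c in (self.left_child, self.right_child) if c is not None]

    def walk(self):
        """Preorder iterator over present nodes."""
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class BinaryVesselTree:
    """One vessel rooted on the optic-disc boundary."""

    vessel_id: str
    root: SegmentNode

    def nodes(self):
        return list(self.root.walk())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes())


@dataclass(frozen=True)
class NormalizationParams:
    """Model-wide scales applied by :func:`vastree.features.normalize_model`."""

    lw_max: float
    angle_scale: float = RIGHT_ANGLE


@dataclass
class TreeModel:
    """Root node (optic disc) plus one binary tree per vessel."""

    od: OpticDiscSpec | None
    trees: list[BinaryVesselTree] = field(default_factory=list)
    normalization: NormalizationParams | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_nodes(self) -> int:
        return sum(t.n_nodes for t in self.trees)

    @property
    def finalized(self) -> bool:
        """True once every node carries a computed feature vector."""
        return all(
            node.features is not None for t in self.trees for node in t.nodes()
        )

    @property
    def angle_scale(self) -> float:
        """Scale of the acute-angle feature: pi/2 raw, 1.0 after
        normalization."""
        if self.normalization is None:
            return RIGHT_ANGLE
        return 1.0
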