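"""Centerline fragmentation, segment tracing and tree-model assembly.

The pipeline: find vessel starting pixels on an annulus just outside the
optic disc, cut the centerline into fragments at landmark *zones*, trace
each fragment by 8-connected region growing with visited flags, continue
straight through crossover zones (a vessel segment appears in two parts at
a crossover and must be re-joined), and assemble one binary tree per
vessel, ordering children so the wider daughter is the left child.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import line

from . import features as _features
from .errors import LandmarkSnapError, TraceError
from .model import (
    BinaryVesselTree,
    SegmentNode,
    TreeModel,
    VesselSegment,
    polyline_length,
)
from .scene import Landmark, VascularScene

log = logging.getLogger(__name__)

#: Chebyshev radius of the boundary zone marked around each landmark.  Two
#: junction arms stay 8-adjacent for a few pixels past the junction, so a
#: radius-1 zone would leave sibling fragments touching; radius 3 cuts them
#: where the generator's minimum inter-daughter angle guarantees separation.
LANDMARK_ZONE_RADIUS = 3

_NEIGHBORS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if dr or dc]


@dataclass(frozen=True)
class BuildConfig:
    """Tunable parameters of the tree builder."""

    zone_radius: int = LANDMARK_ZONE_RADIUS
    direction_window: int = 30  # px used for local direction estimation
    crossover_history: int = 5  # steps averaged for the incoming direction
    max_depth_trace: int = 10  # levels traced below each root
    max_iterations: int | None = None  # default: 10 x image width
    min_daughter_pixels: int = 3  # ignore tinier fragments as daughters
    root_annulus_width: float = 3.0


@dataclass
class Fragmentation:
    """Centerline annotated with landmark boundary zones and fragment labels."""

    centerline: np.ndarray
    boundary: np.ndarray  # True at landmark-zone centerline pixels
    zone_owner: np.ndarray  # landmark index per boundary pixel, -1 elsewhere
    labels: np.ndarray  # fragment id per non-boundary centerline pixel, 0 bg
    n_fragments: int
    landmarks: list[Landmark] = field(default_factory=list)  # snapped copies


def fragment_centerline(
    scene: VascularScene, zone_radius: int = LANDMARK_ZONE_RADIUS
) -> Fragmentation:
    """Cut the centerline into fragments at landmark zones.

    Landmarks more than 2 px off the centerline are snapped to the nearest
    centerline pixel with a warning; beyond 5 px a
    :class:`~vastree.errors.LandmarkSnapError` is raised.
    """
    cl = scene.centerline
    pts = np.argwhere(cl)
    boundary = np.zeros_like(cl)
    zone_owner = np.full(cl.shape, -1, dtype=int)
    snapped: list[Landmark] = []
    tree = cKDTree(pts) if len(pts) else None
    for idx, lm in enumerate(scene.landmarks):
        pos = np.array(lm.position)
        if tree is None:
            raise LandmarkSnapError("landmark on an empty centerline raster")
        d, j = tree.query(pos)
        if d > 5:
            raise LandmarkSnapError(
                f"landmark {lm.klass} at {lm.position} is {d:.1f} px from the "
                "nearest centerline pixel (limit 5)"
            )
        if d > 2:
            log.warning(
                "landmark %s at %s is %.1f px off the centerline; snapping",
                lm.klass, lm.position, d,
            )
        p = tuple(pts[j]) if d > 0 else tuple(pos)
        snapped.append(Landmark((int(p[0]), int(p[1])), lm.klass))
        r0 = max(p[0] - zone_radius, 0)
        r1 = min(p[0] + zone_radius + 1, cl.shape[0])
        c0 = max(p[1] - zone_radius, 0)
        c1 = min(p[1] + zone_radius + 1, cl.shape[1])
        zone = cl[r0:r1, c0:c1]
        sub_owner = zone_owner[r0:r1, c0:c1]
        sub_owner[zone & ~boundary[r0:r1, c0:c1]] = idx
        boundary[r0:r1, c0:c1] |= zone
    labels, n = ndimage.label(cl & ~boundary, structure=np.ones((3, 3)))
    return Fragmentation(cl, boundary, zone_owner, labels, int(n), snapped)


def find_vessel_roots(
    scene: VascularScene, annulus_width: float = 3.0
) -> list[tuple[int, int]]:
    """One starting pixel per vessel crossing the annulus
    ``[radius, radius + annulus_width]`` around the optic-disc centre.

    Adjacent hits are clustered; the representative is the lexicographically
    smallest ``(row, col)``; results are sorted by angle from the OD centre,
    clockwise from 12 o'clock.
    """
    if scene.od is None:
        raise TraceError("scene has no optic-disc specification")
    rr, cc = np.indices(scene.shape)
    orow, ocol = scene.od.center
    dist = np.hypot(rr - orow, cc - ocol)
    annulus = scene.centerline & (dist >= scene.od.radius) & (
        dist <= scene.od.radius + annulus_width
    )
    # Cluster hits: 8-connected components, then merge components whose
    # pixels come within 3 px of each other (a zigzagging line can dip out
    # of the annulus band mid-crossing and split an 8-connected run).
    labels, n = ndimage.label(annulus, structure=np.ones((3, 3)))
    groups = [np.argwhere(labels == k) for k in range(1, n + 1)]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.min(
                np.linalg.norm(
                    groups[i][:, None, :] - groups[j][None, :, :], axis=2
                )
            )
            if d <= 3.0:
                parent[find(j)] = find(i)
    merged: dict[int, list[np.ndarray]] = {}
    for i in range(n):
        merged.setdefault(find(i), []).append(groups[i])
    reps: list[tuple[float, tuple[int, int]]] = []
    for pix_groups in merged.values():
        pix = np.concatenate(pix_groups, axis=0)
        pix = pix[np.lexsort((pix[:, 1], pix[:, 0]))]
        rep = (int(pix[0, 0]), int(pix[0, 1]))
        phi = math.atan2(rep[1] - ocol, -(rep[0] - orow)) % (2 * math.pi)
        reps.append((phi, rep))
    reps.sort()
    return [rep for _, rep in reps]


class _Tracer:
    """Region-growing traversal over a fragmented centerline with shared
    visited flags."""

    def __init__(self, frag: Fragmentation, config: BuildConfig):
        self.frag = frag
        self.config = config
        self.visited = np.zeros_like(frag.centerline)
        self.max_iter = config.max_iterations or 10 * frag.centerline.shape[1]

    # -- low-level helpers -------------------------------------------------
    def _fragment_neighbors(self, p):
        out = []
        nrow, ncol = self.frag.centerline.shape
        for dr, dc in _NEIGHBORS:
            q = (p[0] + dr, p[1] + dc)
            if 0 <= q[0] < nrow and 0 <= q[1] < ncol:
                if (
                    self.frag.centerline[q]
                    and not self.frag.boundary[q]
                    and not self.visited[q]
                ):
                    out.append(q)
        return out

    def _adjacent_landmark(self, p) -> int | None:
        """Index of the landmark whose zone touches pixel ``p``, if any."""
        nrow, ncol = self.frag.centerline.shape
        best = None
        best_d = np.inf
        for dr, dc in _NEIGHBORS:
            q = (p[0] + dr, p[1] + dc)
            if 0 <= q[0] < nrow and 0 <= q[1] < ncol and self.frag.boundary[q]:
                idx = int(self.frag.zone_owner[q])
                if idx < 0:
                    continue
                lm = self.frag.landmarks[idx]
                d = math.hypot(p[0] - lm.position[0], p[1] - lm.position[1])
                if d < best_d:
                    best, best_d = idx, d
        return best

    def _zone_pixels(self, lm_idx: int) -> np.ndarray:
        return np.argwhere(self.frag.zone_owner == lm_idx)

    # -- walking -----------------------------------------------------------
    def walk(self, start, direction_hint):
        """Walk from ``start`` until a splitting landmark, a tip, or the
        iteration cap.  Returns (path, terminating landmark index or None,
        [(crossover landmark index, path index), ...])."""
        path = [tuple(int(x) for x in start)]
        self.visited[path[0]] = True
        recent: list[np.ndarray] = []
        if direction_hint is not None:
            recent.append(np.asarray(direction_hint, dtype=float))
        crossings: list[tuple[int, int]] = []
        term: int | None = None
        for _ in range(self.max_iter):
            cur = path[-1]
            nbrs = self._fragment_neighbors(cur)
            if nbrs:
                nxt = self._choose_step(cur, nbrs, recent)
                recent.append(np.array([nxt[0] - cur[0], nxt[1] - cur[1]], float))
                recent = recent[-self.config.crossover_history:]
                path.append(nxt)
                self.visited[nxt] = True
                continue
            lm_idx = self._adjacent_landmark(cur)
            if lm_idx is None and len(path) > 1:
                lm_idx = self._adjacent_landmark(path[-2])
            if lm_idx is None:
                break  # terminal tip
            lm = self.frag.landmarks[lm_idx]
            if lm.klass in ("bifurcation", "branch"):
                term = lm_idx
                break
            cont = self._crossover_continuation(path, recent, lm_idx)
            if cont is None:
                log.info("no continuation across crossover at %s", lm.position)
                break
            bridge = self._bridge(cur, cont)
            # Record the crossing at the bridge pixel nearest the landmark:
            # tighter than the bridge midpoint, since the landmark position
            # is rounded from the exact crossing point.
            if bridge:
                lp = np.array(lm.position, float)
                off = int(
                    np.argmin(np.linalg.norm(np.array(bridge) - lp, axis=1))
                )
            else:
                off = 0
            crossings.append((lm_idx, len(path) + off))
            for b in bridge:
                path.append(b)
            path.append(cont)
            self.visited[cont] = True
            recent.append(
                np.array([cont[0] - cur[0], cont[1] - cur[1]], float)
            )
            recent = recent[-self.config.crossover_history:]
        return path, term, crossings

    def _choose_step(self, cur, nbrs, recent):
        if len(nbrs) == 1:
            return nbrs[0]
        if not recent:
            return sorted(nbrs)[0]
        incoming = np.mean(recent, axis=0)
        if np.linalg.norm(incoming) < 1e-9:
            return sorted(nbrs)[0]

        def deviation(q):
            v = np.array([q[0] - cur[0], q[1] - cur[1]], float)
            return _angle_between(v, incoming)

        return min(sorted(nbrs), key=deviation)

    def _crossover_continuation(self, path, recent, lm_idx):
        """Pick the fragment pixel across the crossover zone whose outgoing
        direction deviates least from the recent incoming direction."""
        cur = np.array(path[-1], float)
        incoming = (
            np.mean(recent, axis=0) if recent else np.array([0.0, 0.0])
        )
        if np.linalg.norm(incoming) < 1e-9:
            return None
        cur_label = self._label_near(path)
        candidates = {}
        nrow, ncol = self.frag.centerline.shape
        for zr, zc in self._zone_pixels(lm_idx):
            for dr, dc in _NEIGHBORS:
                q = (int(zr + dr), int(zc + dc))
                if not (0 <= q[0] < nrow and 0 <= q[1] < ncol):
                    continue
                if (
                    self.frag.centerline[q]
                    and not self.frag.boundary[q]
                    and not self.visited[q]
                    and self.frag.labels[q] != cur_label
                ):
                    candidates[q] = None
        best, best_dev = None, math.radians(75.0)
        for q in sorted(candidates):
            v = np.array(q, float) - cur
            dev = _angle_between(v, incoming)
            if dev < best_dev:
                best, best_dev = q, dev
        return best

    def _label_near(self, path) -> int:
        for p in reversed(path):
            if self.frag.labels[p] > 0:
                return int(self.frag.labels[p])
        return 0

    def _bridge(self, a, b):
        rr, cc = line(a[0], a[1], b[0], b[1])
        return [(int(r), int(c)) for r, c in zip(rr[1:-1], cc[1:-1])]

    # -- segments ----------------------------------------------------------
    def trace_segment(self, start, incoming_direction=None) -> VesselSegment:
        """Trace the full fragment through ``start`` in both directions.

        The two half-walks are joined so the segment covers its whole
        fragment regardless of where on it the start pixel sits; the path is
        oriented so the terminating landmark (if any) is at the far end.
        """
        start = (int(start[0]), int(start[1]))
        if not self.frag.centerline[start]:
            raise TraceError(f"start pixel {start} is not on the centerline")
        if self.frag.boundary[start]:
            raise TraceError(f"start pixel {start} is a landmark boundary pixel")
        if self.visited[start]:
            raise TraceError(f"start pixel {start} was already traced")
        hint = (
            np.asarray(incoming_direction, dtype=float)
            if incoming_direction is not None
            else None
        )
        path_f, term_f, cross_f = self.walk(start, hint)
        self.visited[start] = False  # allow the backward walk to leave start
        path_b, term_b, cross_b = self.walk(
            start, -hint if hint is not None else None
        )
        # Join: backward part reversed, then forward part.
        back = path_b[1:]
        n_back = len(back)
        path = list(reversed(back)) + path_f
        crossings = [(idx, n_back - 1 - i) for idx, i in cross_b] + [
            (idx, i + n_back) for idx, i in cross_f
        ]
        # The backward walk only defines the terminator if it actually moved:
        # a landmark adjacent to the start pixel itself is the segment's
        # *origin* (its parent junction), not its end.
        term = term_f
        if term is None and term_b is not None and len(path_b) > 1:
            path = list(reversed(path))
            npix = len(path)
            crossings = [(idx, npix - 1 - i) for idx, i in crossings]
            term = term_b
        crossings.sort(key=lambda t: t[1])
        lm = self.frag.landmarks[term] if term is not None else None
        seg = VesselSegment(
            segment_id="",
            path=np.array(path, dtype=int),
            terminating_landmark=lm,
            crossovers_on_path=[
                (self.frag.landmarks[idx], i) for idx, i in crossings
            ],
        )
        # Measure length between the adjacent landmark positions rather than
        # the fragment cut points: where the zone cut falls on the raster
        # jitters by a pixel or two between rasterizations of the same
        # geometry, while the landmark positions are rounded once.
        origin = self._adjacent_landmark(tuple(seg.path[0]))
        if origin is not None:
            olm = self.frag.landmarks[origin]
            seg.origin_landmark = olm
            seg.origin_point = (float(olm.position[0]), float(olm.position[1]))
        if lm is not None:
            seg.terminating_point = (
                float(lm.position[0]), float(lm.position[1])
            )
        _recompute_length(seg)
        return seg

    def daughter_starts(self, lm_idx: int) -> list[tuple[int, int]]:
        """Start pixels of untraced fragments adjacent to a landmark zone."""
        nrow, ncol = self.frag.centerline.shape
        per_fragment: dict[int, list[tuple[float, tuple[int, int]]]] = {}
        lm = self.frag.landmarks[lm_idx]
        for zr, zc in self._zone_pixels(lm_idx):
            for dr, dc in _NEIGHBORS:
                q = (int(zr + dr), int(zc + dc))
                if not (0 <= q[0] < nrow and 0 <= q[1] < ncol):
                    continue
                lab = int(self.frag.labels[q])
                if lab <= 0 or self.visited[q] or self.frag.boundary[q]:
                    continue
                d = math.hypot(q[0] - lm.position[0], q[1] - lm.position[1])
                per_fragment.setdefault(lab, []).append((d, q))
        starts = []
        for lab, cands in sorted(per_fragment.items()):
            size = int(np.sum(self.frag.labels == lab))
            cands.sort()
            starts.append((size, cands[0][1]))
        big = [s for s in starts if s[0] >= self.config.min_daughter_pixels]
        chosen = big if big else starts
        return [pix for _, pix in sorted(chosen, key=lambda t: (-t[0], t[1]))]


def _angle_between(v: np.ndarray, w: np.ndarray) -> float:
    d = float(np.dot(v, w)) / (np.linalg.norm(v) * np.linalg.norm(w))
    return math.acos(max(-1.0, min(1.0, d)))


def _recompute_length(seg: VesselSegment) -> None:
    """Chord length of the path plus extensions to the junction anchors."""
    length = polyline_length(seg.path)
    if seg.origin_point is not None:
        length += math.hypot(
            seg.path[0][0] - seg.origin_point[0],
            seg.path[0][1] - seg.origin_point[1],
        )
    if seg.terminating_point is not None:
        length += math.hypot(
            seg.path[-1][0] - seg.terminating_point[0],
            seg.path[-1][1] - seg.terminating_point[1],
        )
    seg.length_px = length




def trace_segment(
    fragmentation: Fragmentation,
    start: tuple[int, int],
    incoming_direction=None,
    config: BuildConfig = BuildConfig(),
) -> VesselSegment:
    """Trace a single segment (standalone convenience wrapper)."""
    return _Tracer(fragmentation, config).trace_segment(start, incoming_direction)


class _Builder:
    def __init__(self, scene: VascularScene, config: BuildConfig):
        self.scene = scene
        self.config = config
        self.frag = fragment_centerline(scene, config.zone_radius)
        self.tracer = _Tracer(self.frag, config)

    def _width(self, seg: VesselSegment) -> float:
        return _features.segment_avg_width(seg, self.scene.vessel_mask)

    def build_tree(self, root_pixel, vessel_id: str) -> BinaryVesselTree:
        orow, ocol = self.scene.od.center
        hint = np.array([root_pixel[0] - orow, root_pixel[1] - ocol], float)
        seg = self.tracer.trace_segment(root_pixel, hint)
        # Orient root paths outward from the optic disc.
        d0 = math.hypot(seg.path[0][0] - orow, seg.path[0][1] - ocol)
        d1 = math.hypot(seg.path[-1][0] - orow, seg.path[-1][1] - ocol)
        if d0 > d1:
            seg.path = seg.path[::-1].copy()
            npix = len(seg.path)
            seg.crossovers_on_path = [
                (lm, npix - 1 - i) for lm, i in reversed(seg.crossovers_on_path)
            ]
            seg.terminating_landmark, seg.origin_landmark = (
                seg.origin_landmark,
                seg.terminating_landmark,
            )
            seg.sync_endpoints()
        seg.segment_id = f"{vessel_id}s0"
        seg.avg_width_px = self._width(seg)
        root_node = SegmentNode(segment=seg, level=0)
        self._expand(root_node, vessel_id, f"{vessel_id}s0")
        return BinaryVesselTree(vessel_id, root_node)

    def _expand(self, node: SegmentNode, vessel_id: str, sid: str) -> None:
        seg = node.segment
        lm = seg.terminating_landmark
        if lm is None or lm.klass not in ("bifurcation", "branch"):
            return
        if node.level >= self.config.max_depth_trace:
            return
        lm_idx = self.frag.landmarks.index(lm)
        starts = self.tracer.daughter_starts(lm_idx)
        if len(starts) != 2:
            log.warning(
                "landmark %s at %s has %d daughter fragment(s), expected 2",
                lm.klass, lm.position, len(starts),
            )
        daughters = []
        for k, sp in enumerate(starts[:2]):
            hint = np.array(
                [sp[0] - lm.position[0], sp[1] - lm.position[1]], float
            )
            child_seg = self.tracer.trace_segment(sp, hint)
            child_seg.avg_width_px = self._width(child_seg)
            daughters.append(child_seg)
        if not daughters:
            return
        parent_dir = _features.segment_direction(
            seg, at_end=True, window=self.config.direction_window
        )

        def sort_key(s: VesselSegment):
            d = _features.segment_direction(
                s, at_end=False, window=self.config.direction_window
            )
            return (
                -s.avg_width_px,
                _angle_between(d, parent_dir),
                tuple(s.path[0]),
            )

        daughters.sort(key=sort_key)
        children = []
        for k, dseg in enumerate(daughters):
            dseg.segment_id = f"{sid}{k}"
            children.append(SegmentNode(segment=dseg, level=node.level + 1))
        node.left_child = children[0]
        node.right_child = children[1] if len(children) > 1 else None
        for child in node.children:
            self._expand(child, vessel_id, child.segment.segment_id)


def build_vessel_tree(
    scene: VascularScene,
    root_pixel: tuple[int, int],
    config: BuildConfig = BuildConfig(),
    vessel_id: str = "v0",
) -> BinaryVesselTree:
    """Trace one vessel into a binary tree (features not yet computed)."""
    return _Builder(scene, config).build_tree(root_pixel, vessel_id)


def build_tree_model(
    scene: VascularScene, config: BuildConfig = BuildConfig()
) -> TreeModel:
    """Run the full pipeline: roots -> trees -> features -> finalized model."""
    roots = find_vessel_roots(scene, config.root_annulus_width)
    builder = _Builder(scene, config)
    trees = [
        builder.build_tree(rp, f"v{i}") for i, rp in enumerate(roots)
    ]
    model = TreeModel(od=scene.od, trees=trees)
    _features.compute_model_features(model, window=config.direction_window)
    return model
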