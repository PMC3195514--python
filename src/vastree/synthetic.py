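"""Seeded synthetic vascular scenes with exact ground truth.

This module stands in for the upstream image-processing stages (vessel
segmentation, centerline extraction, landmark detection): it generates
scenes of several vessels rooted on the optic-disc boundary, each growing
as a full binary tree of straight segments with decaying widths, with
optional crossings between vessels, and renders them to binary rasters
while keeping the exact topology, widths and landmark classes as ground
truth.

Geometry is sampled first (floats), checked for clearance so that the
rasterized arms of distinct structures never become 8-adjacent, and only
then rasterized.  Everything is driven by one ``numpy`` Generator, so a
given (spec, seed) pair reproduces bit-identical scenes.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import line

from .errors import GenerationError, RotationClipError, SceneSpecError
from .scene import Landmark, OpticDiscSpec, VascularScene

# Internal geometry constants (see docs/methods.md for rationale).
DEPTH_LENGTH_DECAY = 0.9  # segment length multiplier per tree level
SIBLING_WIDTH_FACTOR = 0.7  # extra width factor of the narrow daughter
# Narrow daughters grow slightly longer than their wide siblings: the
# thinner the rendered tube, the more centerline length the subpixel
# width estimate needs for a given relative accuracy.
NARROW_LENGTH_BOOST = 1.3
MIN_INTER_DAUGHTER_ANGLE = 0.9  # rad; keeps rasterized arms separable
WIDE_DAUGHTER_ANGLE = (0.40, 0.55)  # rad, wide daughter vs parent direction
MIN_SEGMENT_CLEARANCE = 6.0  # px between unrelated centerlines
MIN_LANDMARK_SPACING = 16.0  # px between any two landmarks
MIN_CROSSING_ANGLE = math.radians(60.0)
CROSSING_EXTENSION = 20.0  # px a rerouted leaf continues past the crossing
FIT_MARGIN = 6.0  # px kept clear of the rotation-safe radius


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic vascular scene.

    ``branch_angle_range`` bounds the acute angle (radians) between a parent
    and its *narrow* daughter; both bounds must stay below pi/2.
    ``width_decay`` scales a daughter's width relative to its parent; the
    narrow daughter is additionally scaled by 0.7 so the smallest daughter
    is always unique.  ``branch_vs_bifurcation_prob`` is the probability
    that a splitting landmark is classified as a branch (vs bifurcation).
    """

    image_size: int = 512
    od_center: tuple[float, float] | None = None
    od_radius: float = 30.0
    n_vessels: int = 5
    max_depth: int = 2
    root_width: float = 8.0
    width_decay: float = 0.8
    branch_angle_range: tuple[float, float] = (0.5, 1.3)
    segment_length_range: tuple[float, float] = (62.0, 74.0)
    crossover_probability: float = 0.5
    branch_vs_bifurcation_prob: float = 0.5
    seed: int = 0

    @property
    def center(self) -> tuple[float, float]:
        if self.od_center is not None:
            return (float(self.od_center[0]), float(self.od_center[1]))
        c = (self.image_size - 1) / 2.0
        return (c, c)

    def validate(self) -> None:
        if self.n_vessels < 1:
            raise SceneSpecError(f"n_vessels must be >= 1, got {self.n_vessels}")
        if not (0 < self.width_decay <= 1):
            raise SceneSpecError(
                f"width_decay must be in (0, 1], got {self.width_decay}"
            )
        lo, hi = self.branch_angle_range
        if not (0 < lo <= hi < math.pi / 2):
            raise SceneSpecError(
                "branch_angle_range must be acute (strictly below pi/2), "
                f"got {self.branch_angle_range}"
            )
        if not (0 <= self.crossover_probability <= 1):
            raise SceneSpecError("crossover_probability must be in [0, 1]")
        if not (0 <= self.branch_vs_bifurcation_prob <= 1):
            raise SceneSpecError("branch_vs_bifurcation_prob must be in [0, 1]")
        if self.od_radius <= 0:
            raise SceneSpecError("od_radius must be positive")
        reach = self.od_radius + sum(
            self.segment_length_range[1] * DEPTH_LENGTH_DECAY**d
            * (NARROW_LENGTH_BOOST if d == self.max_depth else 1.0)
            for d in range(self.max_depth + 1)
        )
        limit = self._radius_limit()
        if reach > limit:
            raise SceneSpecError(
                f"od_radius + max cumulative segment length ({reach:.0f} px) "
                f"exceeds the usable image radius ({limit:.0f} px); shrink "
                "segment_length_range, od_radius or max_depth, or enlarge "
                "image_size"
            )

    def _radius_limit(self) -> float:
        # Radius from the image centre that survives any rotation <= 45 deg.
        return (self.image_size - 1) / 2.0 - FIT_MARGIN


@dataclass
class TruthSegment:
    """Ground-truth record of one vessel segment (analytic geometry)."""

    segment_id: str
    vessel_id: str
    depth: int
    waypoints: list[np.ndarray]  # float (row, col) points; straight in between
    width: float
    terminal_class: str | None = None  # bifurcation/branch if it splits
    children: list["TruthSegment"] = field(default_factory=list)
    # crossings on this segment: (pixel position, arc-length fraction)
    crossovers: list[tuple[tuple[int, int], float]] = field(default_factory=list)

    @property
    def start(self) -> np.ndarray:
        return self.waypoints[0]

    @property
    def end(self) -> np.ndarray:
        return self.waypoints[-1]

    @property
    def length(self) -> float:
        return sum(
            float(np.linalg.norm(b - a))
            for a, b in zip(self.waypoints[:-1], self.waypoints[1:])
        )

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def sample_points(self, step: float = 1.0) -> np.ndarray:
        """Points along the polyline at roughly ``step`` px spacing."""
        pts = []
        for a, b in zip(self.waypoints[:-1], self.waypoints[1:]):
            seg_len = float(np.linalg.norm(b - a))
            n = max(int(seg_len / step), 1)
            t = np.linspace(0.0, 1.0, n + 1)[:-1]
            pts.append(a[None, :] + t[:, None] * (b - a)[None, :])
        pts.append(self.end[None, :])
        return np.concatenate(pts, axis=0)

    def point_at_fraction(self, frac: float) -> tuple[np.ndarray, np.ndarray]:
        """(point, unit direction) at arc-length fraction ``frac``."""
        target = frac * self.length
        run = 0.0
        for a, b in zip(self.waypoints[:-1], self.waypoints[1:]):
            seg_len = float(np.linalg.norm(b - a))
            if run + seg_len >= target or (a is self.waypoints[-2]):
                u = (b - a) / seg_len
                return a + u * (target - run), u
            run += seg_len
        raise ValueError("empty polyline")  # pragma: no cover


@dataclass
class GroundTruthTopology:
    """Exact topology behind a rendered scene: one tree per vessel plus the
    global landmark list."""

    od: OpticDiscSpec
    image_size: int
    vessels: list[TruthSegment] = field(default_factory=list)
    landmarks: list[Landmark] = field(default_factory=list)

    def segments(self):
        for root in self.vessels:
            yield from root.walk()

    @property
    def n_segments(self) -> int:
        return sum(1 for _ in self.segments())

    def copy(self) -> "GroundTruthTopology":
        return copy.deepcopy(self)


def _dirvec(phi: float) -> np.ndarray:
    """Unit (row, col) vector for an angle measured clockwise from 12
    o'clock (up = decreasing row)."""
    return np.array([-math.cos(phi), math.sin(phi)])


# Orientation guard: all synthetic segment directions sit on a 5-degree
# grid offset by 2.5 degrees.  A thin digital bar aligned (within ~1.5
# degrees) with a raster axis or diagonal is phase-locked: its rendered
# width quantizes to whole pixels and no estimator can recover it to the
# tolerance the matcher uses.  On this grid, every rotation by a multiple
# of 5 degrees keeps every segment at least 2.5 degrees away from such
# degenerate alignments.
_GRID_DEG = 5.0
_GRID_OFFSET_DEG = 2.5


def _snap_phi(phi: float) -> float:
    """Snap an absolute direction onto the offset 5-degree grid."""
    deg = math.degrees(phi)
    return math.radians(round((deg - _GRID_OFFSET_DEG) / _GRID_DEG) * _GRID_DEG
                        + _GRID_OFFSET_DEG)


def _snap_turn(angle: float) -> float:
    """Snap a relative turn onto a multiple of 5 degrees (grid-preserving)."""
    deg = math.degrees(angle)
    return math.radians(max(round(deg / _GRID_DEG), 1) * _GRID_DEG)


def _rotate_vec(v: np.ndarray, ang: float) -> np.ndarray:
    c, s = math.cos(ang), math.sin(ang)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _acute_between(u: np.ndarray, v: np.ndarray) -> float:
    d = abs(float(np.dot(u, v))) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.acos(min(1.0, d))


def _full_angle(u: np.ndarray, v: np.ndarray) -> float:
    d = float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.acos(max(-1.0, min(1.0, d)))


class _VesselSampler:
    """Grows one vessel as a full binary tree of straight segments."""

    def __init__(self, spec: SceneSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.center = np.array(spec.center)
        self.limit = spec._radius_limit()

    def grow(self, vessel_idx: int, base_phi: float) -> TruthSegment | None:
        spec, rng = self.spec, self.rng
        phi = _snap_phi(base_phi + rng.uniform(-0.12, 0.12))
        start = self.center + spec.od_radius * _dirvec(phi)
        vid = f"v{vessel_idx}"
        self._ok = True
        self._base = base_phi
        root = self._segment(start, phi, 0, spec.root_width, vid, f"{vid}s0")
        return root if self._ok else None

    def _segment(self, start, phi, depth, width, vid, sid,
                 length_boost: float = 1.0) -> TruthSegment:
        spec, rng = self.spec, self.rng
        length = (
            rng.uniform(*spec.segment_length_range)
            * DEPTH_LENGTH_DECAY**depth * length_boost
        )
        end = start + length * _dirvec(phi)
        if np.linalg.norm(end - self.center) > self.limit or not self._inside(end):
            self._ok = False
        seg = TruthSegment(sid, vid, depth, [start, end], width)
        if depth < spec.max_depth and self._ok:
            seg.terminal_class = (
                "branch"
                if rng.random() < spec.branch_vs_bifurcation_prob
                else "bifurcation"
            )
            # Narrow daughter turns by the nominal branching angle, wide
            # daughter by a small angle on the opposite side; sides are
            # steered back toward the vessel's base direction to keep the
            # tree inside its angular sector.
            aw = _snap_turn(rng.uniform(*WIDE_DAUGHTER_ANGLE))
            lo = max(spec.branch_angle_range[0], MIN_INTER_DAUGHTER_ANGLE - aw)
            an = _snap_turn(rng.uniform(lo, spec.branch_angle_range[1]))
            drift = phi - self._base
            if abs(drift) < 0.2:
                side = 1.0 if rng.random() < 0.5 else -1.0
            else:
                side = 1.0 if drift > 0 else -1.0  # narrow turns back inward
            wide = self._segment(
                end, phi + side * aw, depth + 1, width * spec.width_decay,
                vid, sid + "0",
            )
            narrow = self._segment(
                end, phi - side * an, depth + 1,
                width * spec.width_decay * SIBLING_WIDTH_FACTOR,
                vid, sid + "1",
                length_boost=(
                    NARROW_LENGTH_BOOST
                    if depth + 1 == spec.max_depth else 1.0
                ),
            )
            seg.children = [wide, narrow]  # left = wide by construction
        return seg

    def _inside(self, p: np.ndarray) -> bool:
        n = self.spec.image_size
        return bool(
            FIT_MARGIN <= p[0] <= n - 1 - FIT_MARGIN
            and FIT_MARGIN <= p[1] <= n - 1 - FIT_MARGIN
        )


def _vessel_clashes(root: TruthSegment, others_tree: cKDTree | None) -> bool:
    """True if the vessel collides with previously accepted vessels or with
    itself (beyond the shared-junction neighbourhoods)."""
    segs = list(root.walk())
    samples = [s.sample_points(1.0) for s in segs]
    if others_tree is not None:
        for pts in samples:
            d, _ = others_tree.query(pts, k=1)
            if float(np.min(d)) < MIN_SEGMENT_CLEARANCE:
                return True
    # Same-vessel pairs.
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            a, b = segs[i], segs[j]
            shared = _shared_junction(a, b)
            pa, pb = samples[i], samples[j]
            if shared is not None:
                pa = pa[np.linalg.norm(pa - shared, axis=1) > 10.0]
                pb = pb[np.linalg.norm(pb - shared, axis=1) > 10.0]
            if len(pa) == 0 or len(pb) == 0:
                continue
            d, _ = cKDTree(pb).query(pa, k=1)
            if float(np.min(d)) < MIN_SEGMENT_CLEARANCE:
                return True
    return False


def _shared_junction(a: TruthSegment, b: TruthSegment) -> np.ndarray | None:
    if b in a.children:
        return a.end
    if a in b.children:
        return b.end
    for p, q in ((a.start, b.start), (a.start, b.end), (a.end, b.start)):
        if np.linalg.norm(p - q) < 1e-9:
            return p
    return None


def _junction_landmarks(truth: GroundTruthTopology) -> list[Landmark]:
    lms = []
    for seg in truth.segments():
        if seg.children:
            r, c = np.rint(seg.end).astype(int)
            lms.append(Landmark((int(r), int(c)), seg.terminal_class))
    return lms


def _sector_violation(root: TruthSegment, center: np.ndarray,
                      base_phi: float, half_width: float) -> bool:
    for seg in root.walk():
        for p in (seg.start, seg.end):
            v = p - center
            phi = math.atan2(v[1], -v[0])
            diff = (phi - base_phi + math.pi) % (2 * math.pi) - math.pi
            if abs(diff) > half_width:
                return True
    return False


def generate_scene(spec: SceneSpec) -> tuple[VascularScene, GroundTruthTopology]:
    """Generate a synthetic scene and its exact ground truth.

    Raises :class:`~vastree.errors.SceneSpecError` if the spec cannot fit
    the image, and :class:`~vastree.errors.GenerationError` if no clash-free
    placement is found under the spec's geometry.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    center = np.array(spec.center)
    od = OpticDiscSpec(spec.center, spec.od_radius)
    sampler = _VesselSampler(spec, rng)

    n = spec.n_vessels
    offset = rng.uniform(0, 2 * math.pi)
    half_sector = max(0.55, 0.85 * math.pi / n) if n > 1 else math.pi
    vessels: list[TruthSegment] = []
    accepted_pts: list[np.ndarray] = []
    junctions: list[np.ndarray] = []
    for i in range(n):
        base_phi = offset + 2 * math.pi * i / n
        tree = cKDTree(np.concatenate(accepted_pts)) if accepted_pts else None
        root = None
        for _ in range(80):
            cand = sampler.grow(i, base_phi)
            if cand is None:
                continue
            if n > 1 and _sector_violation(cand, center, base_phi, half_sector):
                continue
            if _vessel_clashes(cand, tree):
                continue
            cand_junctions = [s.end for s in cand.walk() if s.children]
            if junctions and cand_junctions:
                d, _ = cKDTree(np.array(junctions)).query(
                    np.array(cand_junctions), k=1
                )
                if float(np.min(d)) < MIN_LANDMARK_SPACING:
                    continue
            root = cand
            break
        if root is None:
            raise GenerationError(
                f"could not place vessel {i} of {n} inside image_size="
                f"{spec.image_size} without clashes; the violated bound is "
                f"the {MIN_SEGMENT_CLEARANCE:.0f}-px inter-vessel clearance"
            )
        vessels.append(root)
        accepted_pts.extend(s.sample_points(1.0) for s in root.walk())
        junctions.extend(s.end for s in root.walk() if s.children)

    truth = GroundTruthTopology(od, spec.image_size, vessels)
    truth.landmarks = _junction_landmarks(truth)
    if spec.crossover_probability > 0:
        _add_crossovers(truth, spec, rng)
    scene = render_truth(truth)
    return scene, truth


def _add_crossovers(truth: GroundTruthTopology, spec: SceneSpec,
                    rng: np.random.Generator) -> None:
    """Reroute wide-child leaves through other vessels to create crossings."""
    center = np.array(truth.od.center)
    used: set[str] = set()
    n = len(truth.vessels)
    for i in range(n):
        if rng.random() >= spec.crossover_probability:
            continue
        _try_place_crossover(truth, spec, rng, i, used, center)


def _try_place_crossover(truth, spec, rng, i, used, center) -> bool:
    vessel = truth.vessels[i]
    # Only wide-child leaves are rerouted (see docs/methods.md): inflating
    # the narrow sibling's measured width near a crossing could flip the
    # width order the tree builder sorts children by.
    leaves = [
        s for s in vessel.walk()
        if not s.children and s.segment_id.endswith("0")
        and s.segment_id not in used and not s.crossovers
    ]
    # Only root segments are crossed: a crossing splits the width-profile
    # region of the crossed segment in two, and only the widest, longest
    # segments resolve subpixel width well from the leftover runs.
    targets = [
        v for v in truth.vessels
        if v is not vessel and v.segment_id not in used and not v.crossovers
    ]
    if not leaves or not targets:
        return False
    combos = [(l, t) for l in leaves for t in targets]
    order = rng.permutation(len(combos))
    fractions = (0.5, 0.6, 0.42, 0.68, 0.55)
    for k in order:
        leaf, target = combos[k]
        parent, sibling = _parent_and_sibling(vessel, leaf)
        for frac in fractions:
            plan = _plan_crossing(
                truth, spec, leaf, target, parent, sibling, frac, center
            )
            if plan is None:
                continue
            p_pix, p_float, end = plan
            d_sp = float(np.linalg.norm(p_float - leaf.start))
            total = d_sp + CROSSING_EXTENSION
            leaf.waypoints = [leaf.start, p_float, end]
            leaf.crossovers = [(p_pix, d_sp / total)]
            t_frac = _arc_fraction(target, p_float)
            target.crossovers.append((p_pix, t_frac))
            truth.landmarks.append(Landmark(p_pix, "crossover"))
            used.add(leaf.segment_id)
            used.add(target.segment_id)
            return True
    return False


def _parent_and_sibling(root: TruthSegment, leaf: TruthSegment):
    for seg in root.walk():
        if leaf in seg.children:
            sib = seg.children[0] if seg.children[1] is leaf else seg.children[1]
            return seg, sib
    return None, None


def _arc_fraction(seg: TruthSegment, point: np.ndarray) -> float:
    """Arc-length fraction of the polyline point nearest ``point``."""
    pts = seg.sample_points(0.5)
    d = np.linalg.norm(pts - point, axis=1)
    idx = int(np.argmin(d))
    run = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    return float(run[idx] / run[-1]) if run[-1] > 0 else 0.0


def _plan_crossing(truth, spec, leaf, target, parent, sibling, frac, center):
    limit = spec._radius_limit()
    p0, t_dir = target.point_at_fraction(frac)
    # Keep the crossing away from the target's own endpoints and the OD.
    if min(
        np.linalg.norm(p0 - target.start), np.linalg.norm(p0 - target.end)
    ) < MIN_LANDMARK_SPACING:
        return None
    if np.linalg.norm(p0 - center) < spec.od_radius + 20.0:
        return None
    s = leaf.start
    d_sp = float(np.linalg.norm(p0 - s))
    if not (55.0 <= d_sp <= 170.0):
        return None
    u = (p0 - s) / d_sp
    if _acute_between(u, t_dir) < MIN_CROSSING_ANGLE:
        return None
    # The rerouted leaf must stay separable from its own junction arms.
    p_dir = (parent.end - parent.start) / np.linalg.norm(parent.end - parent.start)
    s_dir = (sibling.end - sibling.start) / np.linalg.norm(
        sibling.end - sibling.start
    )
    if _full_angle(u, s_dir) < MIN_INTER_DAUGHTER_ANGLE:
        return None
    if _full_angle(u, -p_dir) < MIN_INTER_DAUGHTER_ANGLE:
        return None
    end = p0 + CROSSING_EXTENSION * u
    if np.linalg.norm(end - center) > limit:
        return None
    nimg = spec.image_size
    if not (FIT_MARGIN <= end[0] <= nimg - 1 - FIT_MARGIN
            and FIT_MARGIN <= end[1] <= nimg - 1 - FIT_MARGIN):
        return None
    # Landmark spacing.
    for lm in truth.landmarks:
        if np.linalg.norm(p0 - np.array(lm.position, float)) < MIN_LANDMARK_SPACING:
            return None
    # Clearance of the new polyline against everything else.
    new_pts = TruthSegment("tmp", "tmp", 0, [s, end], 1.0).sample_points(1.0)
    keep = (np.linalg.norm(new_pts - s, axis=1) > 10.0) & (
        np.linalg.norm(new_pts - p0, axis=1) > 8.0
    )
    new_kept = new_pts[keep]
    for seg in truth.segments():
        if seg is leaf:
            continue
        pts = seg.sample_points(1.0)
        if seg is target:
            pts = pts[np.linalg.norm(pts - p0, axis=1) > 8.0]
        if seg is parent or seg is sibling:
            pts = pts[np.linalg.norm(pts - s, axis=1) > 10.0]
        if len(pts) == 0 or len(new_kept) == 0:
            continue
        d, _ = cKDTree(pts).query(new_kept, k=1)
        if float(np.min(d)) < MIN_SEGMENT_CLEARANCE:
            return None
    # Snap the crossing point onto an actual raster pixel of the target so
    # the crossover landmark lies on the rendered centerline of both lines,
    # scanning nearby pixels for one that puts the rerouted leaf's direction
    # on the orientation grid (see _snap_phi).
    t_pixels = _raster_pixels(target)
    dists = np.linalg.norm(t_pixels - p0, axis=1)
    near = np.argsort(dists)[:24]
    for k in near:
        if dists[k] > 12.0:
            break
        p_pix_arr = t_pixels[int(k)]
        p_float = p_pix_arr.astype(float)
        d2 = float(np.linalg.norm(p_float - s))
        if d2 < 50.0:
            continue
        u2 = (p_float - s) / d2
        phi_deg = math.degrees(math.atan2(u2[1], -u2[0])) % _GRID_DEG
        if not (2.1 <= phi_deg <= 2.9):
            continue
        if _acute_between(u2, t_dir) < MIN_CROSSING_ANGLE:
            continue
        end2 = p_float + CROSSING_EXTENSION * u2
        if np.linalg.norm(end2 - center) > limit:
            continue
        p_pix = (int(p_pix_arr[0]), int(p_pix_arr[1]))
        return p_pix, p_float, end2
    return None


def _raster_pixels(seg: TruthSegment) -> np.ndarray:
    """Pixels of the segment's rasterized polyline, in path order."""
    pix: list[tuple[int, int]] = []
    wps = [np.rint(w).astype(int) for w in seg.waypoints]
    for a, b in zip(wps[:-1], wps[1:]):
        rr, cc = line(a[0], a[1], b[0], b[1])
        for r, c in zip(rr, cc):
            if not pix or pix[-1] != (int(r), int(c)):
                pix.append((int(r), int(c)))
    return np.array(pix, dtype=int)


def render_truth(truth: GroundTruthTopology) -> VascularScene:
    """Rasterize ground-truth geometry into a scene.

    The centerline is the 1-px Bresenham rasterization of every polyline;
    the vessel mask is the exact tube of each segment: pixels whose centre
    lies within ``width / 2`` of the (float) polyline.  Exact tubes keep the
    rendered width independent of segment orientation, which disk stamping
    at integer pixels does not.
    """
    n = truth.image_size
    cl = np.zeros((n, n), dtype=bool)
    mask = np.zeros((n, n), dtype=bool)
    for seg in truth.segments():
        pix = _raster_pixels(seg)
        cl[pix[:, 0], pix[:, 1]] = True
        radius = max(seg.width / 2.0, 0.6)
        for a, b in zip(seg.waypoints[:-1], seg.waypoints[1:]):
            _paint_tube(mask, a, b, radius)
    return VascularScene(cl, mask, list(truth.landmarks), truth.od)


def _paint_tube(mask: np.ndarray, a: np.ndarray, b: np.ndarray,
                radius: float) -> None:
    """Set pixels whose centre is within ``radius`` of segment ``a``-``b``."""
    n0, n1 = mask.shape
    r0 = max(int(math.floor(min(a[0], b[0]) - radius)), 0)
    r1 = min(int(math.ceil(max(a[0], b[0]) + radius)) + 1, n0)
    c0 = max(int(math.floor(min(a[1], b[1]) - radius)), 0)
    c1 = min(int(math.ceil(max(a[1], b[1]) + radius)) + 1, n1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(
        np.arange(r0, r1), np.arange(c0, c1), indexing="ij"
    )
    pts = np.stack([rr, cc], axis=-1).astype(float)
    ab = b - a
    denom = float(np.dot(ab, ab))
    if denom < 1e-12:
        d = np.linalg.norm(pts - a, axis=-1)
    else:
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
        proj = a[None, None, :] + t[..., None] * ab[None, None, :]
        d = np.linalg.norm(pts - proj, axis=-1)
    mask[r0:r1, c0:c1] |= d <= radius


def rotate_scene(
    scene: VascularScene,
    truth: GroundTruthTopology | None,
    angle: float,
) -> tuple[VascularScene, GroundTruthTopology | None]:
    """Rotate a scene about the image centre by ``angle`` degrees.

    Landmark coordinates, the optic-disc centre and the ground truth are
    rotated analytically, landmarks being rounded to the nearest pixel;
    tree shape and landmark classes are untouched.

    When ground truth is given, the rasters are re-rendered from the
    rotated analytic geometry: rounding the rotated positions to the pixel
    grid is what introduces the discretization error the matcher's +/-5%
    tolerance absorbs, while the centerline stays a valid 1-px-wide
    8-connected raster.  (Nearest-neighbour resampling of a 1-px centerline
    disconnects it wherever the digital line steps diagonally, which no
    tracer could recover from.)  Without ground truth the rasters are
    resampled with nearest-neighbour interpolation, and a rotated
    centerline may lose 8-connectivity.
    """
    if abs(angle) > 45:
        raise ValueError(f"|angle| must be <= 45 degrees, got {angle}")
    if angle == 0:
        return scene.copy(), truth.copy() if truth is not None else None

    nrow, ncol = scene.shape
    c0 = np.array([(nrow - 1) / 2.0, (ncol - 1) / 2.0])
    theta = math.radians(angle)
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )

    def fwd(p: np.ndarray) -> np.ndarray:
        return c0 + rot @ (np.asarray(p, dtype=float) - c0)

    if truth is not None:
        for root in truth.vessels:
            for seg in root.walk():
                for w in seg.waypoints:
                    q = fwd(w)
                    if not (0 <= q[0] <= nrow - 1 and 0 <= q[1] <= ncol - 1):
                        raise RotationClipError(
                            f"rotation by {angle} deg clips vessel "
                            f"{seg.vessel_id} (segment {seg.segment_id})"
                        )

    def round_pt(p: np.ndarray) -> tuple[int, int]:
        q = np.rint(p).astype(int)
        return (int(q[0]), int(q[1]))

    new_truth = None
    if truth is not None:
        new_truth = truth.copy()
        for root in new_truth.vessels:
            for seg in root.walk():
                seg.waypoints = [fwd(w) for w in seg.waypoints]
                seg.crossovers = [
                    (round_pt(fwd(np.array(pos, float))), f)
                    for pos, f in seg.crossovers
                ]
        # Junction landmarks are re-derived from the rotated exact geometry
        # (rounding the already-rounded original positions would land them a
        # pixel off the re-rendered junctions); crossovers are rotated from
        # their stored pixels.
        new_truth.landmarks = _junction_landmarks(new_truth) + [
            Landmark(round_pt(fwd(np.array(lm.position, float))), lm.klass)
            for lm in truth.landmarks
            if lm.klass == "crossover"
        ]
        new_truth.od = OpticDiscSpec(
            tuple(fwd(np.array(truth.od.center))), truth.od.radius
        )
        new_scene = render_truth(new_truth)
        return new_scene, new_truth

    # Inverse mapping for the raster resample: out(q) = in(R^T (q-c0) + c0).
    matrix = rot.T
    offset = c0 - matrix @ c0
    cl = ndimage.affine_transform(
        scene.centerline.astype(np.uint8), matrix, offset=offset, order=0
    ).astype(bool)
    mask = ndimage.affine_transform(
        scene.vessel_mask.astype(np.uint8), matrix, offset=offset, order=0
    ).astype(bool)
    new_landmarks = [
        Landmark(round_pt(fwd(np.array(lm.position, float))), lm.klass)
        for lm in scene.landmarks
    ]
    new_od = None
    if scene.od is not None:
        new_od = OpticDiscSpec(tuple(fwd(np.array(scene.od.center))), scene.od.radius)
    return VascularScene(cl, mask, new_landmarks, new_od), None
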