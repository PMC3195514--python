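"""Invariant feature extraction for tree-model nodes.

All five features are invariant to rotation, translation and uniform
scaling up to raster discretization error: L/W is a ratio of two lengths,
the bifurcation/branch code and crossover flag are discrete, the crossover
position is a ratio of pixel counts along one digital line, and the acute
branching angle is measured between direction estimates fitted to the
centerline on either side of the landmark.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .errors import VastreeError
from .model import (
    RIGHT_ANGLE,
    FeatureVector,
    NormalizationParams,
    SegmentNode,
    TreeModel,
    VesselSegment,
)
from .scene import Landmark

DEFAULT_DIRECTION_WINDOW = 30


def segment_avg_width(
    segment: VesselSegment,
    vessel_mask: np.ndarray,
    trim_ends: int = 9,
    max_halfwidth: float = 5.5,
    chunk: int = 110,
) -> float:
    """Average vessel width along a segment from the binary mask.

    Width is measured as mask *area per unit length*: path pixels are
    grouped into short straight chunks, mask pixels are binned by their
    position along each chunk's axis, and each 1-px bin contributes the
    size of the contiguous covered run around the centerline (capped at
    ``max_halfwidth`` on each side).  Area counting is insensitive to the
    subpixel phase between the vessel and the pixel grid, which point-wise
    distance-transform sampling is not: a thin tube almost aligned with a
    raster axis yields distance values locked to one quantized level, while
    its area still reflects the true width.

    ``trim_ends`` path pixels are excluded at each end that abuts a
    landmark (near a junction the mask is inflated by the parent vessel);
    tip ends need no trimming.  Pixels within 8 px of a crossover are also
    excluded (there the mask is the union of two tubes).
    """
    if segment.path is None or len(segment.path) == 0:
        raise VastreeError("segment has no traced path")
    path = np.asarray(segment.path, dtype=int)
    rows, cols = path[:, 0], path[:, 1]
    inside = vessel_mask[rows, cols]
    if not np.all(inside):
        bad = path[~inside][0]
        raise VastreeError(
            f"path pixel ({bad[0]}, {bad[1]}) lies outside the vessel mask"
        )
    cap = max(0, (len(path) - 7) // 2)
    trim_start = min(trim_ends if segment.origin_landmark is not None else 0, cap)
    trim_end = min(
        trim_ends if segment.terminating_landmark is not None else 0, cap
    )
    keep = np.zeros(len(path), dtype=bool)
    keep[trim_start:len(path) - trim_end if trim_end else len(path)] = True
    for lm, _ in segment.crossovers_on_path:
        d = np.hypot(rows - lm.position[0], cols - lm.position[1])
        keep &= d > 8.0
    if not np.any(keep):
        keep = np.ones(len(path), dtype=bool)
    widths: list[float] = []
    # Maximal kept runs, split into chunks short enough to be straight.
    idx = np.flatnonzero(keep)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    # A crossover exclusion splits the segment into runs; short leftovers
    # resolve the boundary poorly, so when a long run exists use long runs
    # only.
    longest = max((len(r) for r in runs), default=0)
    if longest >= 25:
        runs = [r for r in runs if len(r) >= 25]
    for run in runs:
        if len(run) < 3:
            continue
        n_chunks = max(1, -(-len(run) // chunk))  # balanced, each <= chunk
        for part in np.array_split(run, n_chunks):
            if len(part) < 3:
                continue
            widths.extend(
                _chunk_profile_widths(
                    vessel_mask, path[part].astype(float), max_halfwidth
                )
            )
    if len(widths) >= 7:
        # A few bins can be contaminated by a neighbouring tube entering
        # the profile window near a junction; such bins jut out by the
        # foreign tube's thickness, far beyond the sawtooth spread of the
        # clean per-bin estimates, so gate on distance to the median.
        arr = np.asarray(widths)
        med = float(np.median(arr))
        good = arr[np.abs(arr - med) <= 2.0]
        return float(np.mean(good))
    if not widths:
        # Degenerate (very short) segment: fall back to the local distance
        # transform, which needs no straight-chunk geometry.
        pad = int(max_halfwidth) + 3
        r0 = max(int(rows.min()) - pad, 0)
        r1 = min(int(rows.max()) + pad + 1, vessel_mask.shape[0])
        c0 = max(int(cols.min()) - pad, 0)
        c1 = min(int(cols.max()) + pad + 1, vessel_mask.shape[1])
        edt = ndimage.distance_transform_edt(vessel_mask[r0:r1, c0:c1])
        return float(np.mean(2.0 * edt[rows - r0, cols - c0]))
    return float(np.mean(widths))


def _chunk_profile_widths(
    mask: np.ndarray, pts: np.ndarray, max_halfwidth: float
) -> list[float]:
    """Subpixel width of one straight path chunk by boundary midpoints.

    The chunk's pixels are binned by position along the fitted axis.  In
    each 1-px bin and on each side, the tube boundary lies between the
    outermost covered pixel and the innermost uncovered pixel beyond it;
    the midpoint of that pair estimates the boundary with an error that is
    an unbiased sawtooth in the subpixel phase, so averaging the per-bin
    two-sided widths over the chunk cancels it.  Using both sides inside
    one bin also cancels any tilt of the fitted axis relative to the true
    tube axis, which single-sided extremes would inherit.
    """
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    u = vt[0]
    if float(np.dot(u, pts[-1] - pts[0])) < 0:
        u = -u
    nvec = np.array([-u[1], u[0]])
    along_path = centered @ u
    lo, hi = float(along_path.min()), float(along_path.max())
    pad = max_halfwidth + 2.5
    r0 = max(int(np.floor(pts[:, 0].min() - pad)), 0)
    r1 = min(int(np.ceil(pts[:, 0].max() + pad)) + 1, mask.shape[0])
    c0 = max(int(np.floor(pts[:, 1].min() - pad)), 0)
    c1 = min(int(np.ceil(pts[:, 1].max() + pad)) + 1, mask.shape[1])
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    q = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float) - centroid
    along = q @ u
    perp = q @ nvec
    covered = mask[rr.ravel(), cc.ravel()]
    sel = np.abs(perp) <= max_halfwidth + 1.5
    along, perp, covered = along[sel], perp[sel], covered[sel]
    inside = (along >= lo + 1.0) & (along <= hi - 1.0)
    along, perp, covered = along[inside], perp[inside], covered[inside]
    bins = np.floor(along).astype(int)
    # Per-bin two-sided boundary midpoints; they gate contaminated bins and
    # serve as the fallback estimate for very short chunks.
    mids: dict[int, float] = {}
    for b in np.unique(bins):
        m = bins == b
        p, c = perp[m], covered[m]
        pc = p[c & (np.abs(p) <= max_halfwidth)]
        if len(pc) == 0:
            continue
        ub, lb = float(pc.max()), float(pc.min())
        above = p[~c & (p > ub)]
        below = p[~c & (p < lb)]
        if not len(above) or not len(below):
            continue
        mids[b] = (ub + float(above.min()) - lb - float(below.max())) / 2.0
    if not mids:
        return []
    med = float(np.median(list(mids.values())))
    good_bins = {b for b, w in mids.items() if abs(w - med) <= 2.0}
    n_bins = len(good_bins)
    if n_bins < 14:
        # Too few cross-sections to pin a shared tilt; per-bin midpoints
        # are the more stable estimate here.
        return [w for b, w in mids.items() if b in good_bins]
    keep = np.isin(bins, list(good_bins))
    along, perp, covered = along[keep], perp[keep], covered[keep]
    # Joint boundary fit: for a straight tube, a pixel is covered iff its
    # perpendicular offset lies within the two boundary lines (a shared
    # residual tilt t relative to the fitted axis, and one offset per
    # side).  For each candidate tilt the covered pixels give a lower
    # bound and the uncovered pixels an upper bound on each boundary
    # offset; the tilt maximizing the joint feasibility margin pins both
    # boundaries to a fraction of a pixel, because the constraint phases
    # drift along the chunk.
    # The scan must cover the PCA axis error (about one pixel of end-to-end
    # wobble over the chunk span) but no more, or short chunks overfit the
    # tilt to a spuriously large margin.
    span = max(hi - lo, 8.0)
    t_max = min(max(0.02, 1.3 / span), 0.06)
    ts = np.linspace(-t_max, t_max, 61)
    up_cov = covered & (np.abs(perp) <= max_halfwidth)
    p_cov, a_cov = perp[up_cov], along[up_cov]
    unc_above = ~covered & (perp > 0)
    unc_below = ~covered & (perp < 0)
    if not np.any(unc_above) or not np.any(unc_below) or not np.any(up_cov):
        return [w for b, w in mids.items() if b in good_bins]
    adj_cov = p_cov[None, :] - ts[:, None] * a_cov[None, :]
    hi_up = np.array(
        [np.min(perp[unc_above] - t * along[unc_above]) for t in ts]
    )
    lo_up = adj_cov.max(axis=1)
    hi_dn = np.array(
        [np.min(-(perp[unc_below]) + t * along[unc_below]) for t in ts]
    )
    lo_dn = (-adj_cov).max(axis=1)
    # Most robustly feasible tilt: maximize the smaller side margin, so
    # both boundary brackets are strictly satisfied at the chosen tilt.
    joint = np.minimum(hi_up - lo_up, hi_dn - lo_dn)
    k = int(np.argmax(joint))
    if joint[k] <= 0:
        return [w for b, w in mids.items() if b in good_bins]
    width_fit = (lo_up[k] + hi_up[k]) / 2.0 + (lo_dn[k] + hi_dn[k]) / 2.0
    # Blend with the per-bin midpoint average: the joint fit's residual
    # bias peaks near diagonal orientations (locked 2-D lattice phases at
    # the extremes of the brackets), the per-bin average's near the raster
    # axes (too little phase drift across bins); averaging the two halves
    # whichever bias is active.
    width_bins = float(np.mean([mids[b] for b in good_bins]))
    width = (width_fit + width_bins) / 2.0
    return [float(width)] * n_bins


def lw_ratio(segment: VesselSegment) -> float:
    """Length-to-width ratio of a traced segment."""
    if segment.avg_width_px <= 0:
        raise VastreeError(
            f"segment {segment.segment_id or '<anon>'} has zero average width"
        )
    return segment.length_px / segment.avg_width_px


def encode_landmark(landmark: Landmark) -> int:
    """1 for a bifurcation, 0 for a branch."""
    if landmark.klass == "bifurcation":
        return 1
    if landmark.klass == "branch":
        return 0
    raise VastreeError(
        f"{landmark.klass!r} is not a terminating landmark class "
        "(crossovers do not terminate segments)"
    )


def crossover_features(segment: VesselSegment) -> tuple[int, float]:
    """(flag, relative position) of the first crossover on the segment.

    The position is the pixel index of the crossover divided by the
    segment's pixel count, so a 100-pixel segment crossed at its 70th pixel
    yields 0.7; segments without a crossover yield (0, 0).
    """
    if not segment.crossovers_on_path:
        return 0, 0.0
    idx = min(i for _, i in segment.crossovers_on_path)
    n = segment.n_pixels or (len(segment.path) if segment.path is not None else 0)
    if n <= 0:
        raise VastreeError("segment has no pixels")
    return 1, float(idx) / float(n)


def segment_direction(
    segment: VesselSegment, at_end: bool, window: int = DEFAULT_DIRECTION_WINDOW
) -> np.ndarray:
    """Unit direction of the centerline near one end of a segment.

    Fits a total-least-squares line (PCA) through the ``window`` path pixels
    nearest the requested end and orients it along the walk.  Falls back to
    the endpoint difference for very short segments.
    """
    path = np.asarray(segment.path, dtype=float)
    pts = path[-window:] if at_end else path[:window]
    if len(pts) < 3:
        v = path[-1] - path[0] if at_end else path[0] - path[-1]
        n = np.linalg.norm(v)
        if n < 1e-9:
            return np.array([1.0, 0.0])
        return v / n
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    along = pts[-1] - pts[0]
    if float(np.dot(d, along)) < 0:
        d = -d
    return d / np.linalg.norm(d)


def acute_angle(
    parent: VesselSegment,
    daughters: list[VesselSegment],
    window: int = DEFAULT_DIRECTION_WINDOW,
) -> float:
    """Acute angle between the widest and narrowest vessel at a landmark.

    The parent and its daughters are sorted by average width; the angle is
    measured between the direction of the widest and of the narrowest,
    each estimated from the path pixels nearest the landmark.
    """
    if not daughters:
        raise VastreeError("acute_angle requires at least one daughter")
    members = [(parent, True)] + [(d, False) for d in daughters]
    members.sort(key=lambda m: -m[0].avg_width_px)
    (wide_seg, wide_at_end), (narrow_seg, narrow_at_end) = members[0], members[-1]
    u = segment_direction(wide_seg, at_end=wide_at_end, window=window)
    v = segment_direction(narrow_seg, at_end=narrow_at_end, window=window)
    d = abs(float(np.dot(u, v)))
    return math.acos(min(1.0, d))


def build_feature_vector(
    node: SegmentNode,
    daughters: list[VesselSegment] | None = None,
    window: int = DEFAULT_DIRECTION_WINDOW,
) -> FeatureVector:
    """Assemble the 5-tuple for one node (L/W, Bi/Br, crossover flag,
    crossover position, acute angle)."""
    seg = node.segment
    if daughters is None:
        daughters = [c.segment for c in node.children]
    flag, pos = crossover_features(seg)
    lm = seg.terminating_landmark
    if daughters and lm is not None:
        bibr = encode_landmark(lm)
        angle = acute_angle(seg, daughters, window=window)
    else:
        bibr = 0
        angle = 0.0
    return FeatureVector(
        lw_ratio=lw_ratio(seg),
        bibr_code=bibr,
        crossover_flag=flag,
        crossover_pos=pos,
        acute_angle=angle,
    )


def compute_model_features(
    model: TreeModel, window: int = DEFAULT_DIRECTION_WINDOW
) -> TreeModel:
    """Compute feature vectors for every node of every tree, in place."""
    for tree in model.trees:
        for node in tree.root.walk():
            node.features = build_feature_vector(node, window=window)
    return model


def normalize_model(model: TreeModel) -> tuple[TreeModel, NormalizationParams]:
    """Scale every L/W by the model-wide maximum and every angle by pi/2.

    Idempotent: a model that already carries normalization parameters is
    returned unchanged.  Matching results do not depend on whether both
    compared models are normalized, because the matcher's tolerances are
    relative (L/W) or rescaled by the stored angle scale (angle).
    """
    if model.normalization is not None:
        return model, model.normalization
    vectors = [
        node.features for t in model.trees for node in t.root.walk()
        if node.features is not None
    ]
    if not vectors:
        params = NormalizationParams(lw_max=1.0)
        return TreeModel(model.od, [], params), params
    lw_max = max(v.lw_ratio for v in vectors)
    if lw_max <= 0:
        raise VastreeError("cannot normalize a model with non-positive L/W")
    params = NormalizationParams(lw_max=lw_max)

    def scale(node: SegmentNode) -> SegmentNode:
        f = node.features
        new = SegmentNode(
            segment=node.segment,
            features=FeatureVector(
                lw_ratio=f.lw_ratio / lw_max,
                bibr_code=f.bibr_code,
                crossover_flag=f.crossover_flag,
                crossover_pos=f.crossover_pos,
                acute_angle=f.acute_angle / RIGHT_ANGLE,
            )
            if f is not None
            else None,
            level=node.level,
        )
        if node.left_child is not None:
            new.left_child = scale(node.left_child)
        if node.right_child is not None:
            new.right_child = scale(node.right_child)
        return new

    from .model import BinaryVesselTree  # local import to avoid clutter

    trees = [
        BinaryVesselTree(t.vessel_id, scale(t.root)) for t in model.trees
    ]
    return TreeModel(model.od, trees, params), params
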