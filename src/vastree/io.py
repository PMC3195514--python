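"""On-disk formats for scenes, tree models and distance matrices.

A scene directory holds ``centerline.png`` and ``mask.png`` (binary PNG,
0/255), ``landmarks.json`` and ``od.json``; the synthetic generator adds
``truth.json``.  Tree models are versioned JSON, distance matrices CSV.
All coordinates are 0-based (row, col) with the origin at the top-left,
and every writer is deterministic byte-for-byte for equal inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ModelFormatError, SceneFormatError
from .matching import DistanceMatrix
from .model import (
    BinaryVesselTree,
    FeatureVector,
    NormalizationParams,
    SegmentNode,
    TreeModel,
    VesselSegment,
)
from .scene import Landmark, OpticDiscSpec, VascularScene
from .synthetic import GroundTruthTopology, TruthSegment

FORMAT_VERSION = "1"
_CONVENTION = "0-based (row, col), origin top-left"

SCENE_FILES = ("centerline.png", "mask.png", "landmarks.json", "od.json")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def write_scene(scene: VascularScene, directory) -> None:
    """Write the four scene files into ``directory`` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in (("centerline.png", scene.centerline),
                      ("mask.png", scene.vessel_mask)):
        img = Image.fromarray((arr.astype(np.uint8)) * 255, mode="L")
        img.save(directory / name)
    _write_json(
        directory / "landmarks.json",
        {
            "format_version": FORMAT_VERSION,
            "coordinate_convention": _CONVENTION,
            "landmarks": [
                {"row": lm.position[0], "col": lm.position[1], "class": lm.klass}
                for lm in scene.landmarks
            ],
        },
    )
    od = scene.od
    _write_json(
        directory / "od.json",
        {
            "coordinate_convention": _CONVENTION,
            "row": od.center[0],
            "col": od.center[1],
            "radius": od.radius,
        },
    )


def read_scene(directory) -> VascularScene:
    """Read and validate a scene directory; rasters binarized at > 0."""
    directory = Path(directory)
    for name in SCENE_FILES:
        if not (directory / name).exists():
            raise SceneFormatError(f"missing scene file: {directory / name}")
    cl = np.asarray(Image.open(directory / "centerline.png")) > 0
    mask = np.asarray(Image.open(directory / "mask.png")) > 0
    raw = json.loads((directory / "landmarks.json").read_text())
    entries = raw["landmarks"] if isinstance(raw, dict) else raw
    landmarks = [
        Landmark((int(e["row"]), int(e["col"])), e["class"]) for e in entries
    ]
    od_raw = json.loads((directory / "od.json").read_text())
    od = OpticDiscSpec((od_raw["row"], od_raw["col"]), od_raw["radius"])
    return VascularScene(cl, mask, landmarks, od)


# -- ground truth ------------------------------------------------------------

def write_truth(truth: GroundTruthTopology, path) -> None:
    def seg_dict(seg: TruthSegment) -> dict:
        return {
            "segment_id": seg.segment_id,
            "vessel_id": seg.vessel_id,
            "depth": seg.depth,
            "waypoints": [[float(w[0]), float(w[1])] for w in seg.waypoints],
            "width": float(seg.width),
            "terminal_class": seg.terminal_class,
            "crossovers": [
                {"row": int(p[0]), "col": int(p[1]), "fraction": float(f)}
                for p, f in seg.crossovers
            ],
            "children": [seg_dict(c) for c in seg.children],
        }

    _write_json(
        Path(path),
        {
            "format_version": FORMAT_VERSION,
            "coordinate_convention": _CONVENTION,
            "image_size": truth.image_size,
            "od": {
                "row": truth.od.center[0],
                "col": truth.od.center[1],
                "radius": truth.od.radius,
            },
            "landmarks": [
                {"row": lm.position[0], "col": lm.position[1], "class": lm.klass}
                for lm in truth.landmarks
            ],
            "vessels": [seg_dict(v) for v in truth.vessels],
        },
    )


def read_truth(path) -> GroundTruthTopology:
    raw = json.loads(Path(path).read_text())

    def seg_from(d: dict) -> TruthSegment:
        seg = TruthSegment(
            segment_id=d["segment_id"],
            vessel_id=d["vessel_id"],
            depth=int(d["depth"]),
            waypoints=[np.array(w, dtype=float) for w in d["waypoints"]],
            width=float(d["width"]),
            terminal_class=d["terminal_class"],
        )
        seg.crossovers = [
            ((int(c["row"]), int(c["col"])), float(c["fraction"]))
            for c in d["crossovers"]
        ]
        seg.children = [seg_from(c) for c in d["children"]]
        return seg

    od = OpticDiscSpec((raw["od"]["row"], raw["od"]["col"]), raw["od"]["radius"])
    truth = GroundTruthTopology(
        od,
        int(raw["image_size"]),
        [seg_from(v) for v in raw["vessels"]],
        [
            Landmark((int(e["row"]), int(e["col"])), e["class"])
            for e in raw["landmarks"]
        ],
    )
    return truth


# -- tree models -------------------------------------------------------------

def write_tree_model(model: TreeModel, path) -> None:
    """Serialize a finalized tree model to versioned JSON.

    Each node carries its five feature values in column order
    (L/W, Bi/Br, Crossover, Cross pos., Acute angle).
    """
    if not model.finalized:
        raise ModelFormatError(
            "tree model is not finalized: some nodes have no features"
        )

    def node_dict(node: SegmentNode) -> dict:
        seg = node.segment
        return {
            "segment_id": seg.segment_id if seg else "",
            "level": node.level,
            "start": [int(x) for x in seg.start]
            if seg is not None and seg.start is not None
            else None,
            "end": [int(x) for x in seg.end]
            if seg is not None and seg.end is not None
            else None,
            "n_pixels": int(seg.n_pixels) if seg else 0,
            "length_px": float(seg.length_px) if seg else 0.0,
            "avg_width_px": float(seg.avg_width_px) if seg else 0.0,
            "features": [float(x) for x in node.features.as_tuple()],
            "left": node_dict(node.left_child) if node.left_child else None,
            "right": node_dict(node.right_child) if node.right_child else None,
        }

    payload = {
        "format_version": FORMAT_VERSION,
        "coordinate_convention": _CONVENTION,
        "od": None
        if model.od is None
        else {
            "row": model.od.center[0],
            "col": model.od.center[1],
            "radius": model.od.radius,
        },
        "normalization": None
        if model.normalization is None
        else {
            "lw_max": model.normalization.lw_max,
            "angle_scale": model.normalization.angle_scale,
        },
        "trees": [
            {"vessel_id": t.vessel_id, "root": node_dict(t.root)}
            for t in model.trees
        ],
    }
    _write_json(Path(path), payload)


def read_tree_model(path) -> TreeModel:
    raw = json.loads(Path(path).read_text())
    version = raw.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported tree-model format_version {version!r}; "
            f"expected {FORMAT_VERSION!r}"
        )

    def node_from(d: dict, level: int) -> SegmentNode:
        seg = VesselSegment(
            segment_id=d["segment_id"],
            path=None,
            n_pixels=int(d["n_pixels"]),
            length_px=float(d["length_px"]),
            avg_width_px=float(d["avg_width_px"]),
            start=tuple(d["start"]) if d.get("start") is not None else None,
            end=tuple(d["end"]) if d.get("end") is not None else None,
        )
        lw, bibr, flag, pos, angle = d["features"]
        node = SegmentNode(
            segment=seg,
            features=FeatureVector(
                lw_ratio=float(lw),
                bibr_code=int(bibr),
                crossover_flag=int(flag),
                crossover_pos=float(pos),
                acute_angle=float(angle),
            ),
            level=level,
        )
        if d["left"] is not None:
            node.left_child = node_from(d["left"], level + 1)
        if d["right"] is not None:
            node.right_child = node_from(d["right"], level + 1)
        return node

    od = None
    if raw["od"] is not None:
        od = OpticDiscSpec((raw["od"]["row"], raw["od"]["col"]), raw["od"]["radius"])
    norm = None
    if raw.get("normalization") is not None:
        norm = NormalizationParams(
            lw_max=float(raw["normalization"]["lw_max"]),
            angle_scale=float(raw["normalization"]["angle_scale"]),
        )
    trees = [
        BinaryVesselTree(t["vessel_id"], node_from(t["root"], 0))
        for t in raw["trees"]
    ]
    return TreeModel(od, trees, norm)


# -- distance matrices -------------------------------------------------------

def write_distance_matrix(matrix: DistanceMatrix, path) -> None:
    """Write a square labelled matrix as CSV (labels quoted as needed)."""
    if not matrix.is_square:
        raise ModelFormatError(
            f"distance matrix must be square, got shape {matrix.values.shape}"
        )
    df = pd.DataFrame(
        matrix.values, index=matrix.row_labels, columns=matrix.col_labels
    )
    df.to_csv(Path(path), lineterminator="\n")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(Path(path), index_col=0)
    return DistanceMatrix(
        [str(x) for x in df.index],
        [str(x) for x in df.columns],
        df.to_numpy(dtype=int),
    )
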