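"""Core scene types: rasters, landmarks and the optic-disc specification.

A *vascular scene* is the input world of the tool: a 1-pixel-wide binary
centerline raster, a filled binary vessel mask, a list of labelled landmark
points (bifurcation / branch / crossover), and the optic-disc circle from
which every vessel originates.  Coordinates are 0-based ``(row, col)`` with
the origin at the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SceneFormatError

#: The three landmark classes.  A bifurcation splits a vessel into two
#: comparable daughters, a branch is a minor vessel leaving a major one,
#: and a crossover is a 2-D projection crossing of two distinct vessels.
LANDMARK_CLASSES = ("bifurcation", "branch", "crossover")


@dataclass(frozen=True)
class Landmark:
    """A labelled vascular landmark at a pixel position."""

    position: tuple[int, int]
    klass: str

    def __post_init__(self) -> None:
        if self.klass not in LANDMARK_CLASSES:
            raise SceneFormatError(
                f"unknown landmark class {self.klass!r}; "
                f"expected one of {LANDMARK_CLASSES}"
            )
        object.__setattr__(
            self, "position", (int(self.position[0]), int(self.position[1]))
        )


@dataclass(frozen=True)
class OpticDiscSpec:
    """Optic-disc circle: vessels are rooted on its boundary."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise SceneFormatError(f"optic-disc radius must be > 0, got {self.radius}")
        object.__setattr__(
            self, "center", (float(self.center[0]), float(self.center[1]))
        )


@dataclass
class VascularScene:
    """Rasters + landmarks + optic disc; the validated input of the pipeline."""

    centerline: np.ndarray
    vessel_mask: np.ndarray
    landmarks: list[Landmark] = field(default_factory=list)
    od: OpticDiscSpec | None = None

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline) > 0
        self.vessel_mask = np.asarray(self.vessel_mask) > 0
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return self.centerline.shape

    def validate(self) -> None:
        if self.centerline.ndim != 2:
            raise SceneFormatError("centerline raster must be 2-D")
        if self.centerline.shape != self.vessel_mask.shape:
            raise SceneFormatError(
                f"raster size mismatch: centerline {self.centerline.shape} "
                f"vs vessel mask {self.vessel_mask.shape}"
            )
        nrow, ncol = self.centerline.shape
        for lm in self.landmarks:
            r, c = lm.position
            if not (0 <= r < nrow and 0 <= c < ncol):
                raise SceneFormatError(
                    f"landmark {lm.klass} at {lm.position} outside "
                    f"raster bounds {self.centerline.shape}"
                )

    def copy(self) -> "VascularScene":
        return VascularScene(
            self.centerline.copy(),
            self.vessel_mask.copy(),
            list(self.landmarks),
            self.od,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VascularScene):
            return NotImplemented
        return (
            np.array_equal(self.centerline, other.centerline)
            and np.array_equal(self.vessel_mask, other.vessel_mask)
            and self.landmarks == other.landmarks
            and self.od == other.od
        )
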