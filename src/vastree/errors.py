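"""Exception hierarchy for vastree."""


class VastreeError(Exception):
    """Base class for all vastree errors."""


class SceneSpecError(VastreeError, ValueError):
    """A synthetic scene specification violates its invariants."""


class GenerationError(VastreeError, RuntimeError):
    """Synthetic geometry could not be placed inside the stated bounds."""


class RotationClipError(VastreeError, ValueError):
    """Rotating a scene would push a vessel outside the image."""


class SceneFormatError(VastreeError, ValueError):
    """An on-disk scene is missing files or violates validation rules."""


class LandmarkSnapError(VastreeError, ValueError):
    """A landmark lies too far from any centerline pixel to be snapped."""


class TraceError(VastreeError, RuntimeError):
    """Centerline traversal was started from an invalid pixel."""


class ModelFormatError(VastreeError, ValueError):
    """A serialized tree model or distance matrix is malformed."""
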