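"""Instance segmentation of spheroids with a pluggable backend contract.

The shipped backend is a deterministic classical pipeline built on edge and
opacity cues: cystic spheroids present either an opaque (darker than
background) body or, when fully viable and transparent, a thin dark rim.
The pipeline thresholds a combined boundary-evidence map with hysteresis,
fills the enclosed lumen, and compensates for the rim band so the reported
mask approximates the lumen interior.

Learned region-proposal backends (e.g. a fine-tuned Mask R-CNN) plug in
through the same registry; their masks pass through the same shared
minimum-area filter.  Overlap splitting via watershed is available but off
by default — distance-transform splitting is unreliable for strongly
overlapping bodies, which is precisely where a learned backend is the
better tool.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigurationError, ValidationError
from .io import GrayImage


@dataclass
class InstanceMask:
    """One segmented spheroid: boolean pixel membership on the image grid."""

    mask: np.ndarray
    label: int
    confidence: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.label < 1:
            raise ValidationError("instance labels start at 1")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError("confidence must lie in [0, 1]")
        if not self.mask.any():
            raise ValidationError("instance masks must be non-empty")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class SegmentationResult:
    """All instances found in one image, plus provenance of the backend."""

    instances: list[InstanceMask]
    backend_name: str
    params_digest: str

    def __post_init__(self) -> None:
        labels = [i.label for i in self.instances]
        if len(labels) != len(set(labels)):
            raise ValidationError("instance labels must be unique within an image")

    def union_mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        if self.instances:
            out = np.zeros_like(self.instances[0].mask)
            for inst in self.instances:
                out |= inst.mask
            return out
        if shape is None:
            raise ValidationError("shape required for the union of an empty result")
        return np.zeros(shape, dtype=bool)


@dataclass(frozen=True)
class ClassicalParams:
    """Tunables of the classical backend.

    ``rim_sensitivity`` scales the hysteresis thresholds on the boundary
    evidence map (lower = more sensitive); ``rim_compensation_px`` is the
    erosion applied to each filled component to strip the dark rim band and
    its smoothing halo, matched to ``smooth_sigma`` and a ~2 px rim.
    """

    smooth_sigma: float = 1.0
    rim_sensitivity: float = 1.0
    min_area_px: int = 64
    split_overlaps: bool = False
    rim_compensation_px: int = 3

    def __post_init__(self) -> None:
        vals = (self.smooth_sigma, self.rim_sensitivity, self.rim_compensation_px)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("classical parameters must be finite")
        if self.smooth_sigma < 0 or self.rim_sensitivity <= 0:
            raise ValidationError("smooth_sigma >= 0 and rim_sensitivity > 0 required")
        if self.min_area_px < 0 or self.rim_compensation_px < 0:
            raise ValidationError("area and erosion parameters must be >= 0")


# evidence thresholds (intensity units) at rim_sensitivity = 1.0
_EVIDENCE_LOW = 12.0
_EVIDENCE_HIGH = 30.0


def _digest(params) -> str:
    payload = repr(sorted(asdict(params).items())) if hasattr(params, "__dataclass_fields__") \
        else repr(params)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _split_component(component: np.ndarray) -> list[np.ndarray]:
    """Distance-transform watershed split of one merged component."""
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    dist = ndi.distance_transform_edt(component)
    min_sep = max(4, int(dist.max() * 0.7))
    peaks = peak_local_max(dist, min_distance=min_sep, labels=component,
                           exclude_border=False)
    if len(peaks) <= 1:
        return [component]
    markers = np.zeros(component.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    ws = watershed(-dist, markers, mask=component)
    return [ws == lab for lab in range(1, len(peaks) + 1) if (ws == lab).any()]


def segment_classical(image: GrayImage,
                      params: ClassicalParams | None = None) -> SegmentationResult:
    """Deterministic classical spheroid segmentation.

    Stages: Gaussian smooth -> median background level -> boundary evidence
    (gradient magnitude combined with darker-than-background response) ->
    hysteresis threshold -> hole filling -> connected components ->
    optional distance-transform splitting -> rim compensation (erosion) ->
    minimum-area filter.  A pure function of (image, params).
    """
    if params is None:
        params = ClassicalParams()
    from skimage.filters import apply_hysteresis_threshold

    img = image.pixels.astype(np.float64)
    sm = ndi.gaussian_filter(img, params.smooth_sigma) if params.smooth_sigma > 0 else img
    background = float(np.median(sm))
    darkness = np.clip(background - sm, 0.0, None)
    gy = ndi.sobel(sm, axis=0)
    gx = ndi.sobel(sm, axis=1)
    grad = np.hypot(gy, gx) / 4.0  # sobel gain ~4 per intensity-unit step
    evidence = np.maximum(darkness, grad)

    low = _EVIDENCE_LOW * params.rim_sensitivity
    high = _EVIDENCE_HIGH * params.rim_sensitivity
    fg = apply_hysteresis_threshold(evidence, low, high)
    fg = ndi.binary_fill_holes(fg)

    labeled, n = ndi.label(fg)
    components = [labeled == lab for lab in range(1, n + 1)]
    if params.split_overlaps:
        split: list[np.ndarray] = []
        for comp in components:
            split.extend(_split_component(comp))
        components = split

    instances: list[InstanceMask] = []
    label = 1
    erosion = params.rim_compensation_px
    structure = ndi.generate_binary_structure(2, 2)
    for comp in components:
        if erosion > 0:
            comp = ndi.binary_erosion(comp, structure=structure, iterations=erosion)
        if comp.sum() >= max(1, params.min_area_px):
            instances.append(InstanceMask(mask=comp, label=label, confidence=1.0))
            label += 1
    return SegmentationResult(instances=instances, backend_name="classical",
                              params_digest=_digest(params))


def _maskrcnn_backend(image: GrayImage, params) -> SegmentationResult:
    """Adapter for a fine-tuned region-proposal instance model (optional).

    Requires the ``torch``/``torchvision`` optional dependency and a model
    artifact path in ``params``; raises a configuration error otherwise.
    """
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise ConfigurationError(
            "the maskrcnn backend requires the optional torch/torchvision "
            "dependencies and a trained model artifact") from exc
    if not isinstance(params, dict) or "model_path" not in params:
        raise ConfigurationError(
            "no model artifact configured for the maskrcnn backend; "
            "pass params={'model_path': ...}")
    raise NotImplementedError(
        "inference adapter requires a packaged model artifact")


BACKENDS: dict[str, Callable] = {
    "classical": segment_classical,
    "maskrcnn": _maskrcnn_backend,
}


def segment(image: GrayImage, backend: str = "classical",
            params=None) -> SegmentationResult:
    """Dispatch to a registered backend and apply the shared min-area filter."""
    if backend not in BACKENDS:
        raise ConfigurationError(
            f"unknown segmentation backend {backend!r}; "
            f"registered: {sorted(BACKENDS)}")
    result = BACKENDS[backend](image, params)
    min_area = getattr(params, "min_area_px", None)
    if min_area is None and isinstance(params, dict):
        min_area = params.get("min_area_px")
    if min_area:
        kept = [i for i in result.instances if i.area_px >= min_area]
        for new_label, inst in enumerate(kept, start=1):
            inst.label = new_label
        result = SegmentationResult(kept, result.backend_name, result.params_digest)
    return result


def finetune_instance_model(train_images, train_annotations,
                            config: dict | None = None):
    """Fine-tune a pretrained general instance-segmentation model (optional).

    Transfer learning from a COCO-pretrained Mask R-CNN: the default
    schedule trains 20 epochs, records per-epoch validation losses, and
    selects the checkpoint with the lowest validation loss.  Requires the
    optional torch/torchvision dependencies.
    """
    if not train_images:
        raise ValidationError("training requires at least one annotated image")
    if train_annotations is None or len(train_annotations) != len(train_images):
        raise ValidationError("one annotation record per training image is required")
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise ConfigurationError(
            "fine-tuning requires the optional torch/torchvision dependencies; "
            "install them to enable the maskrcnn backend") from exc
    raise NotImplementedError(
        "training loop not bundled; see the maskrcnn adapter documentation")


def polygons_to_masks(polygons: list[list[tuple[float, float]]],
                      shape: tuple[int, int]) -> list[np.ndarray]:
    """Rasterize annotator polygon vertex lists ((row, col) pairs) to masks."""
    from skimage.draw import polygon as _sk_polygon

    masks = []
    for verts in polygons:
        if len(verts) < 3:
            raise ValidationError("polygons need at least three vertices")
        rows = [v[0] for v in verts]
        cols = [v[1] for v in verts]
        rr, cc = _sk_polygon(rows, cols, shape=shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        masks.append(m)
    return masks
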