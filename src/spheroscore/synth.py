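"""Seeded synthetic brightfield scenes of cystic spheroids with known truth.

The generator emulates the image phenotype the scoring model is built on:
a bright, roughly uniform gel background; spheroids rendered as disks whose
interior brightness encodes viability (transparent lumen = viable, opaque =
dead) with a thin darker rim giving the "distinct circular edge" cue; and
three nuisance layers applied after ground truth is captured — a radial
vignette, opaque nanoparticle speckle, and Gaussian sensor noise.

Interior intensity is the exact inverse of the scoring map: a spheroid with
viability ``V`` on background ``B`` is rendered at ``clip(B - (100 - V) /
0.4, 0, 255)``, so scoring a noise-free scene with the true masks recovers
the planted viabilities up to 8-bit quantization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import STANDARD_SIZE, GrayImage, ImageMeta, vignette_field

#: viability percentage encoded by one 8-bit intensity unit of opacity
PCT_PER_INTENSITY_UNIT = 0.4

#: intensity painted into nanoparticle speckle blobs (opaque = dark)
SPECKLE_INTENSITY = 25.0

_MAX_PLACEMENT_TRIES = 400


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``viabilities`` may be an explicit per-spheroid list (length
    ``n_spheroids``) or ``None`` to sample uniformly on [0, 100].
    Radii are in microns and converted with ``microns_per_pixel``.
    """

    n_spheroids: int = 5
    radius_um_range: tuple[float, float] = (100.0, 300.0)
    viabilities: tuple[float, ...] | None = None
    background_intensity: float = 200.0
    gaussian_noise_sigma: float = 0.0
    speckle_density: float = 0.0
    speckle_radius_px_range: tuple[float, float] = (1.0, 4.0)
    allow_overlap: bool = False
    vignette_strength: float = 0.0
    seed: int = 0
    image_size: int = STANDARD_SIZE
    microns_per_pixel: float = 2.5
    rim_width_px: float = 2.0
    rim_depth: float = 60.0
    centroid_jitter_um: float = 0.0

    def __post_init__(self) -> None:
        if self.n_spheroids < 0:
            raise ValidationError("n_spheroids must be >= 0")
        rmin, rmax = self.radius_um_range
        if rmin <= 0 or rmax < rmin:
            raise ValidationError(f"invalid radius_um_range {self.radius_um_range}")
        if self.viabilities is not None:
            object.__setattr__(self, "viabilities", tuple(float(v) for v in self.viabilities))
            if len(self.viabilities) != self.n_spheroids:
                raise ValidationError("viabilities length must equal n_spheroids")
            if any(not 0.0 <= v <= 100.0 for v in self.viabilities):
                raise ValidationError("viabilities must lie in [0, 100]")
        if not 0.0 <= self.speckle_density <= 1.0:
            raise ValidationError("speckle_density must lie in [0, 1]")
        if not 0.0 <= self.vignette_strength < 1.0:
            raise ValidationError("vignette_strength must lie in [0, 1)")
        if self.gaussian_noise_sigma < 0:
            raise ValidationError("gaussian_noise_sigma must be >= 0")
        if not 0.0 <= self.background_intensity <= 255.0:
            raise ValidationError("background_intensity must lie in [0, 255]")
        if self.microns_per_pixel <= 0:
            raise ValidationError("microns_per_pixel must be > 0")
        if rmin / self.microns_per_pixel < 1.0:
            raise ValidationError("minimum radius is below one pixel at this calibration")


@dataclass(frozen=True)
class Perturbation:
    """A treatment applied after imaging on ``day``: viability then drops by
    ``viability_drop_per_day`` percentage points per subsequent day, floored
    at zero."""

    day: int
    viability_drop_per_day: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError("perturbation day must be >= 0")
        if self.viability_drop_per_day < 0:
            raise ValidationError("viability_drop_per_day must be >= 0")


@dataclass
class GroundTruthScene:
    """Per-instance truth for a rendered scene, captured before noise."""

    instance_masks: list[np.ndarray]
    viabilities: list[float]
    centroids: list[tuple[float, float]]
    areas_px: list[int]
    lineage_ids: list[int]

    def __post_init__(self) -> None:
        n = len(self.instance_masks)
        for other in (self.viabilities, self.centroids, self.areas_px, self.lineage_ids):
            if len(other) != n:
                raise ValidationError("truth lists must have equal length")
        for m in self.instance_masks:
            if not m.any():
                raise ValidationError("truth masks must be non-empty")

    @property
    def n(self) -> int:
        return len(self.instance_masks)


def interior_intensity(viability: float, background: float) -> float:
    """Interior brightness encoding ``viability`` on ``background``."""
    return float(np.clip(background - (100.0 - viability) / PCT_PER_INTENSITY_UNIT,
                         0.0, 255.0))


def viability_floor(background: float) -> float:
    """Lowest viability representable without clipping the interior at 0.

    On a background of ``B`` the interior can darken by at most ``B`` units,
    i.e. ``100 - 0.4 * B`` percent.  The default sampling rule draws from
    this representable range so that rendered scenes invert exactly;
    explicit viability lists may go below it, in which case the interior
    clips at 0 and the planted value is not recoverable by scoring.
    """
    return max(0.0, 100.0 - PCT_PER_INTENSITY_UNIT * background)


def _place_instances(rng: np.random.Generator, radii_px: np.ndarray,
                     clearance_px: np.ndarray, size: int,
                     allow_overlap: bool) -> list[tuple[float, float]]:
    """Sample centers; rejection-sample for disjointness unless overlap is allowed."""
    centers: list[tuple[float, float]] = []
    for i, r in enumerate(radii_px):
        margin = clearance_px[i] + 2.0
        if 2 * margin >= size:
            raise ValidationError(
                f"spheroid radius {r:.0f}px too large for a {size}px image")
        for _ in range(_MAX_PLACEMENT_TRIES):
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            if allow_overlap or all(
                math.hypot(cy - oy, cx - ox) > clearance_px[i] + clearance_px[j] + 1.0
                for j, (oy, ox) in enumerate(centers)
            ):
                centers.append((cy, cx))
                break
        else:
            raise ValidationError(
                "could not place all spheroids without overlap; "
                "set allow_overlap=True or reduce n_spheroids/radii")
    return centers


def _render(size: int, background: float, centers: Sequence[tuple[float, float]],
            radii_px: Sequence[float], viabilities: Sequence[float],
            rim_width: float, rim_depth: float) -> tuple[np.ndarray, list[np.ndarray]]:
    """Paint instances in order (later occludes earlier); return float canvas
    and full-extent truth masks (interior disks, rim excluded)."""
    canvas = np.full((size, size), float(background))
    masks: list[np.ndarray] = []
    rim_val = max(0.0, background - rim_depth)
    for (cy, cx), r, v in zip(centers, radii_px, viabilities):
        r_out = r + rim_width
        r0 = max(0, int(math.floor(cy - r_out - 1)))
        r1 = min(size, int(math.ceil(cy + r_out + 2)))
        c0 = max(0, int(math.floor(cx - r_out - 1)))
        c1 = min(size, int(math.ceil(cx + r_out + 2)))
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dist = np.hypot(yy - cy, xx - cx)
        rim_px = dist <= r_out
        int_px = dist <= r
        view = canvas[r0:r1, c0:c1]
        view[rim_px] = rim_val
        view[int_px] = interior_intensity(v, background)
        mask = np.zeros((size, size), dtype=bool)
        mask[r0:r1, c0:c1] = int_px
        masks.append(mask)
    return canvas, masks


def _apply_noise(canvas: np.ndarray, spec: SceneSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Vignette -> speckle -> Gaussian noise, then 8-bit quantization."""
    out = canvas.copy()
    if spec.vignette_strength > 0:
        out = out * vignette_field(out.shape, spec.vignette_strength)
    if spec.speckle_density > 0:
        rmin, rmax = spec.speckle_radius_px_range
        mean_r2 = (rmin**2 + rmin * rmax + rmax**2) / 3.0
        n_blobs = int(round(spec.speckle_density * out.size / (math.pi * mean_r2)))
        size = out.shape[0]
        for _ in range(n_blobs):
            cy = rng.uniform(0, size)
            cx = rng.uniform(0, size)
            r = rng.uniform(rmin, rmax)
            r0 = max(0, int(cy - r - 1)); r1 = min(size, int(cy + r + 2))
            c0 = max(0, int(cx - r - 1)); c1 = min(size, int(cx + r + 2))
            yy, xx = np.mgrid[r0:r1, c0:c1]
            out[r0:r1, c0:c1][np.hypot(yy - cy, xx - cx) <= r] = SPECKLE_INTENSITY
    if spec.gaussian_noise_sigma > 0:
        out = out + rng.normal(0.0, spec.gaussian_noise_sigma, out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def generate_scene(spec: SceneSpec,
                   meta: ImageMeta | None = None) -> tuple[GrayImage, GroundTruthScene]:
    """Render one scene; ground truth reflects the pre-noise geometry.

    Deterministic: the same spec always yields bit-identical image and truth.
    """
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_spheroids
    rmin, rmax = spec.radius_um_range
    radii_px = rng.uniform(rmin, rmax, n) / spec.microns_per_pixel
    if spec.viabilities is not None:
        viab = np.asarray(spec.viabilities, dtype=float)
    else:
        viab = rng.uniform(viability_floor(spec.background_intensity), 100.0, n)
    clearance = radii_px + spec.rim_width_px
    centers = _place_instances(rng, radii_px, clearance, spec.image_size,
                               spec.allow_overlap)
    canvas, masks = _render(spec.image_size, spec.background_intensity, centers,
                            radii_px, viab, spec.rim_width_px, spec.rim_depth)
    truth = GroundTruthScene(
        instance_masks=masks,
        viabilities=[float(v) for v in viab],
        centroids=[(cy, cx) for cy, cx in centers],
        areas_px=[int(m.sum()) for m in masks],
        lineage_ids=list(range(n)),
    )
    pixels = _apply_noise(canvas, spec, rng)
    if meta is None:
        meta = ImageMeta(well_id="SIM", day=0)
    return GrayImage(pixels=pixels, meta=meta), truth


def generate_longitudinal_series(
    spec: SceneSpec,
    days: int,
    growth_rate: float = 1.0,
    perturbation: Perturbation | None = None,
    well_id: str = "SIM",
    group: str | None = None,
    z_um: float | None = None,
) -> list[tuple[GrayImage, GroundTruthScene]]:
    """Render a multi-day series sharing one spheroid population.

    Radii grow geometrically by ``growth_rate`` per day; after
    ``perturbation.day`` viabilities fall by ``viability_drop_per_day`` per
    day, floored at 0.  Lineage ids are stable across days.  Per-day noise
    streams are derived deterministically from ``spec.seed`` and the day.
    """
    if days < 1:
        raise ValidationError("days must be >= 1")
    if growth_rate <= 0:
        raise ValidationError("growth_rate must be > 0")
    if perturbation is not None and perturbation.day > days:
        raise ValidationError("perturbation.day exceeds the series length")

    base = np.random.default_rng([spec.seed, 0])
    n = spec.n_spheroids
    rmin, rmax = spec.radius_um_range
    radii0 = base.uniform(rmin, rmax, n) / spec.microns_per_pixel
    if spec.viabilities is not None:
        viab0 = np.asarray(spec.viabilities, dtype=float)
    else:
        viab0 = base.uniform(viability_floor(spec.background_intensity), 100.0, n)
    # reserve room for the final-day radii so growing spheroids stay in frame
    final_scale = max(1.0, growth_rate ** (days - 1))
    clearance = radii0 * final_scale + spec.rim_width_px
    centers0 = _place_instances(base, radii0, clearance, spec.image_size,
                                spec.allow_overlap)

    series: list[tuple[GrayImage, GroundTruthScene]] = []
    jitter_px = spec.centroid_jitter_um / spec.microns_per_pixel
    for day in range(1, days + 1):
        day_rng = np.random.default_rng([spec.seed, day])
        radii = radii0 * growth_rate ** (day - 1)
        if perturbation is not None:
            days_past = max(0, day - perturbation.day)
            viab = np.maximum(0.0, viab0 - perturbation.viability_drop_per_day * days_past)
        else:
            viab = viab0
        if jitter_px > 0:
            offs = day_rng.normal(0.0, jitter_px, (n, 2))
        else:
            offs = np.zeros((n, 2))
        centers = [(cy + dy, cx + dx) for (cy, cx), (dy, dx) in zip(centers0, offs)]
        canvas, masks = _render(spec.image_size, spec.background_intensity, centers,
                                radii, viab, spec.rim_width_px, spec.rim_depth)
        truth = GroundTruthScene(
            instance_masks=masks,
            viabilities=[float(v) for v in viab],
            centroids=centers,
            areas_px=[int(m.sum()) for m in masks],
            lineage_ids=list(range(n)),
        )
        pixels = _apply_noise(canvas, spec, day_rng)
        meta = ImageMeta(well_id=well_id, day=day, z_um=z_um, group=group)
        series.append((GrayImage(pixels=pixels, meta=meta), truth))
    return series


def generate_z_stack(spec: SceneSpec, z_planes_um: Sequence[float],
                     well_id: str = "SIM", day: int = 0,
                     group: str | None = None) -> list[tuple[GrayImage, GroundTruthScene]]:
    """Independent scenes sharing one spec, one per focal plane.

    Planes are generated independently (no 3-D rendering); each plane's seed
    is derived from ``spec.seed`` and the plane index.
    """
    stack = []
    for i, z in enumerate(z_planes_um):
        plane_spec = replace(spec, seed=spec.seed + 1000 + i)
        meta = ImageMeta(well_id=well_id, day=day, z_um=float(z), group=group)
        stack.append(generate_scene(plane_spec, meta=meta))
    return stack
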