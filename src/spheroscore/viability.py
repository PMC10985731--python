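"""Intensity-to-viability scoring and per-image summaries.

The scoring model exploits the cystic-spheroid phenotype: a healthy
spheroid has an open, transparent lumen, so in brightfield its interior
transmits as much light as the surrounding gel; dead material is opaque and
dark.  The score is a linear map from mean interior opacity (background
minus mean interior intensity) to percent viability at 0.4 percentage
points per 8-bit intensity unit, clamped to [0, 100] and reported at 0.1%
resolution.  Equivalently, the full 0-100% range spans a 250-unit
intensity drop below background.

An image with no detected spheroids reports the sentinel average viability
of -1.  The sentinel encodes absence, not a score, and must never enter a
group mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import Calibration, GrayImage, ImageMeta
from .segmentation import InstanceMask, SegmentationResult

#: percent viability per 8-bit unit of interior opacity
PCT_PER_INTENSITY_UNIT = 0.4

#: reported average viability of an image with no spheroids
SENTINEL_NO_SPHEROID = -1.0

#: CSV schema for per-spheroid records
SPHEROID_CSV_COLUMNS = [
    "image", "well_id", "day", "z_um", "group", "label", "viability_pct",
    "area_um2", "radius_um", "centroid_row", "centroid_col",
    "mean_interior_intensity", "background_intensity",
]

#: CSV schema for per-image summaries
IMAGE_CSV_COLUMNS = [
    "image", "well_id", "day", "z_um", "group", "n_spheroids",
    "avg_viability", "avg_viability_unweighted", "avg_area_um2", "avg_radius_um",
]


@dataclass
class SpheroidRecord:
    """Viability and morphology of a single segmented spheroid."""

    label: int
    viability_pct: float
    area_um2: float
    radius_um: float
    centroid: tuple[float, float]
    mean_interior_intensity: float
    background_intensity: float
    meta: ImageMeta

    def __post_init__(self) -> None:
        if not 0.0 <= self.viability_pct <= 100.0:
            raise ValidationError("viability_pct must lie in [0, 100]")
        if self.area_um2 <= 0 or self.radius_um <= 0:
            raise ValidationError("area and radius must be positive")


@dataclass
class WellSummary:
    """Per-image aggregate; ``avg_viability`` is -1 iff no spheroids."""

    n_spheroids: int
    avg_viability: float
    avg_viability_unweighted: float | None
    avg_area_um2: float | None
    avg_radius_um: float | None
    meta: ImageMeta

    def __post_init__(self) -> None:
        if (self.n_spheroids == 0) != (self.avg_viability == SENTINEL_NO_SPHEROID):
            raise ValidationError(
                "avg_viability must be the -1 sentinel exactly when n_spheroids == 0")

    @property
    def has_spheroids(self) -> bool:
        return self.n_spheroids > 0


def background_intensity(image: GrayImage,
                         segmentation: SegmentationResult) -> float:
    """Median intensity over all pixels outside every instance mask.

    The median makes the estimate robust to dark nanoparticle speckle in
    the gel.
    """
    outside = ~segmentation.union_mask(image.pixels.shape)
    if not outside.any():
        raise ValidationError(
            "masks cover the entire image; background is undefined")
    return float(np.median(image.pixels[outside]))


def spheroid_viability(image: GrayImage, mask: InstanceMask | np.ndarray,
                       background: float) -> float:
    """Score one spheroid from its mean interior intensity.

    ``V = clamp(100 - 0.4 * max(0, background - mean_interior), 0, 100)``
    rounded to 0.1%.  Interiors brighter than background clamp to 100.
    """
    m = mask.mask if isinstance(mask, InstanceMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValidationError("cannot score an empty mask")
    mean_interior = float(image.pixels[m].mean())
    opacity = max(0.0, background - mean_interior)
    v = 100.0 - PCT_PER_INTENSITY_UNIT * opacity
    return round(max(0.0, min(100.0, v)), 1)


def classify_live_dead(viability_pct: float, threshold: float = 0.0) -> str:
    """Binary live/dead call: live iff viability strictly exceeds threshold.

    The default threshold of 0 mirrors the usual binary assay readout; it
    can be raised (e.g. to a few percent) to match coarser raters.
    """
    if not 0.0 <= threshold < 100.0:
        raise ValidationError(f"threshold must lie in [0, 100), got {threshold}")
    if not 0.0 <= viability_pct <= 100.0:
        raise ValidationError("viability must lie in [0, 100]")
    return "live" if viability_pct > threshold else "dead"


def summarize_image(
    image: GrayImage,
    segmentation: SegmentationResult,
    calibration: Calibration,
) -> tuple[WellSummary, list[SpheroidRecord]]:
    """Score every instance and aggregate to a per-image summary.

    The whole-image average viability is weighted by instance area (larger
    spheroids carry proportionally more tissue); the plain mean is emitted
    alongside it.  An empty segmentation yields the sentinel summary.
    """
    if calibration is None:
        raise ConfigurationError("a Calibration (microns per pixel) is required")
    meta = image.meta
    if not segmentation.instances:
        return WellSummary(0, SENTINEL_NO_SPHEROID, None, None, None, meta), []

    bg = background_intensity(image, segmentation)
    mpp2 = calibration.microns_per_pixel ** 2
    records: list[SpheroidRecord] = []
    for inst in segmentation.instances:
        area_px = inst.area_px
        area_um2 = area_px * mpp2
        rows, cols = np.nonzero(inst.mask)
        records.append(SpheroidRecord(
            label=inst.label,
            viability_pct=spheroid_viability(image, inst, bg),
            area_um2=area_um2,
            radius_um=math.sqrt(area_um2 / math.pi),
            centroid=(float(rows.mean()), float(cols.mean())),
            mean_interior_intensity=float(image.pixels[inst.mask].mean()),
            background_intensity=bg,
            meta=meta,
        ))
    areas = np.array([r.area_um2 for r in records])
    viab = np.array([r.viability_pct for r in records])
    summary = WellSummary(
        n_spheroids=len(records),
        avg_viability=round(float(np.average(viab, weights=areas)), 1),
        avg_viability_unweighted=round(float(viab.mean()), 1),
        avg_area_um2=float(areas.mean()),
        avg_radius_um=float(np.mean([r.radius_um for r in records])),
        meta=meta,
    )
    return summary, records


# ---------------------------------------------------------------------------
# tidy-table conversion (CSV schemas)
# ---------------------------------------------------------------------------

def _meta_fields(meta: ImageMeta) -> dict:
    return {
        "image": meta.source_path,
        "well_id": meta.well_id,
        "day": meta.day,
        "z_um": meta.z_um if meta.z_um is not None else np.nan,
        "group": meta.group if meta.group is not None else "",
    }


def records_to_frame(records: list[SpheroidRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = _meta_fields(r.meta)
        row.update(
            label=r.label, viability_pct=r.viability_pct, area_um2=r.area_um2,
            radius_um=r.radius_um, centroid_row=r.centroid[0],
            centroid_col=r.centroid[1],
            mean_interior_intensity=r.mean_interior_intensity,
            background_intensity=r.background_intensity,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=SPHEROID_CSV_COLUMNS)


def summaries_to_frame(summaries: list[WellSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = _meta_fields(s.meta)
        row.update(
            n_spheroids=s.n_spheroids,
            avg_viability=s.avg_viability,
            avg_viability_unweighted=(
                s.avg_viability_unweighted if s.avg_viability_unweighted is not None
                else np.nan),
            avg_area_um2=s.avg_area_um2 if s.avg_area_um2 is not None else np.nan,
            avg_radius_um=s.avg_radius_um if s.avg_radius_um is not None else np.nan,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=IMAGE_CSV_COLUMNS)


def group_mean_viability(summaries: list[WellSummary]) -> float:
    """Mean avg_viability over summaries, excluding sentinel entries."""
    vals = [s.avg_viability for s in summaries if s.has_spheroids]
    if not vals:
        raise ValidationError("no non-sentinel summaries to average")
    return float(np.mean(vals))
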