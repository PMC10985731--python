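"""Image input, standardization, calibration, and file output.

All downstream analysis operates on a single standardized representation:
an 8-bit grayscale frame resized to 1024x1024, regardless of the camera or
export format the image came from.  Brightfield viability scoring only needs
relative intensity against the local background, so the standardization is
deliberately aggressive: RGB is collapsed with ITU-R 601 luma weights,
16-bit frames are rescaled by their maximum, and everything is resampled
bilinearly to the working grid.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .errors import ImageIOError, ValidationError

#: side length of the standardized working grid, in pixels
STANDARD_SIZE = 1024

#: ITU-R 601 luma weights used for RGB -> grayscale conversion
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_FILENAME_RE = re.compile(
    r"^(?P<well>[A-Za-z][A-Za-z0-9]*)"
    r"_d(?P<day>\d+)"
    r"(?:_z(?P<z>\d+(?:\.\d+)?))?"
    r"(?:_(?P<group>[A-Za-z0-9][A-Za-z0-9.\-]*))?$"
)


@dataclass(frozen=True)
class ImageMeta:
    """Acquisition metadata attached to a standardized image."""

    source_path: str = ""
    well_id: str = ""
    day: int = 0
    z_um: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError(f"day must be >= 0, got {self.day}")
        if self.z_um is not None and self.z_um < 0:
            raise ValidationError(f"z_um must be >= 0, got {self.z_um}")


@dataclass
class GrayImage:
    """Standardized 8-bit grayscale image plus acquisition metadata.

    ``pixels`` is a 2-D uint8 array; after :func:`standardize` the shape is
    always ``(STANDARD_SIZE, STANDARD_SIZE)``.
    """

    pixels: np.ndarray
    meta: ImageMeta = field(default_factory=ImageMeta)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("GrayImage requires a non-empty 2-D pixel array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValidationError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration of the standardized grid.

    The instruments this pipeline targets do not embed a scale in their
    exports, so microns-per-pixel is a required run configuration value.
    The default of 2.5 um/px is a documented placeholder and should be set
    from the microscope's objective and the resize factor for real data.
    """

    microns_per_pixel: float = 2.5
    intensity_depth: int = 255

    def __post_init__(self) -> None:
        if not np.isfinite(self.microns_per_pixel) or self.microns_per_pixel <= 0:
            raise ValidationError(
                f"microns_per_pixel must be > 0, got {self.microns_per_pixel}"
            )


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, C]) array to a float 2-D luminance map on [0, 255]."""
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 3:
        if a.shape[2] == 4:  # drop alpha
            a = a[:, :, :3]
        if a.shape[2] == 3:
            a = a @ np.asarray(LUMA_WEIGHTS)
        elif a.shape[2] == 1:
            a = a[:, :, 0]
        else:
            raise ValidationError(f"unsupported channel count {a.shape[2]}")
    elif a.ndim != 2:
        raise ValidationError(f"unsupported image dimensionality {a.ndim}")
    return a


def _rescale_to_uint8_range(a: np.ndarray, source_dtype: np.dtype) -> np.ndarray:
    """Map a luminance array to [0, 255] floats depending on the source depth."""
    if np.issubdtype(source_dtype, np.integer) and source_dtype.itemsize > 1:
        peak = a.max()
        if peak > 0:
            a = a * (255.0 / peak)
    elif np.issubdtype(source_dtype, np.floating):
        if a.max() <= 1.0:
            a = a * 255.0
    return np.clip(a, 0.0, 255.0)


def standardize(arr: np.ndarray, size: int = STANDARD_SIZE) -> np.ndarray:
    """Convert an arbitrary decoded image array to the uint8 working grid.

    Grayscale conversion, depth rescaling, bilinear resize to ``size`` x
    ``size``, then round-half-even quantization.  Idempotent: an already
    standardized frame passes through unchanged.
    """
    src = np.asarray(arr)
    if src.size == 0:
        raise ValidationError("cannot standardize a zero-sized image")
    a = to_grayscale(src)
    a = _rescale_to_uint8_range(a, src.dtype)
    if a.shape != (size, size):
        a = _sk_resize(a, (size, size), order=1, anti_aliasing=False,
                       preserve_range=True, mode="edge")
    return np.clip(np.rint(a), 0, 255).astype(np.uint8)


def parse_filename_metadata(path: str | Path) -> ImageMeta:
    """Parse ``<well>_d<day>[_z<um>][_<group>].<ext>`` into an :class:`ImageMeta`.

    Unparseable names fall back to a bare record carrying only the path.
    """
    p = Path(path)
    m = _FILENAME_RE.match(p.stem)
    if m is None:
        return ImageMeta(source_path=str(p))
    return ImageMeta(
        source_path=str(p),
        well_id=m.group("well"),
        day=int(m.group("day")),
        z_um=float(m.group("z")) if m.group("z") is not None else None,
        group=m.group("group"),
    )


def load_manifest(path: str | Path) -> dict[str, ImageMeta]:
    """Read a CSV manifest mapping image filenames to acquisition metadata.

    Expected columns: ``filename, well_id, day`` and optionally
    ``z_um, group``.  Returns a dict keyed by filename (no directory).
    """
    df = pd.read_csv(path)
    required = {"filename", "well_id", "day"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    out: dict[str, ImageMeta] = {}
    for row in df.itertuples(index=False):
        z = getattr(row, "z_um", None)
        g = getattr(row, "group", None)
        out[str(row.filename)] = ImageMeta(
            source_path=str(row.filename),
            well_id=str(row.well_id),
            day=int(row.day),
            z_um=None if z is None or pd.isna(z) else float(z),
            group=None if g is None or (isinstance(g, float) and pd.isna(g)) else str(g),
        )
    return out


def load_image(path: str | Path, meta: ImageMeta | None = None) -> GrayImage:
    """Read a TIFF/PNG/JPG file and return the standardized grayscale frame.

    Metadata defaults to whatever the filename convention yields; pass
    ``meta`` (e.g. from a manifest) to override.
    """
    p = Path(path)
    try:
        raw = iio.imread(p)
    except FileNotFoundError:
        raise ImageIOError(f"image file not found: {p}") from None
    except Exception as exc:  # decoder errors vary by plugin
        raise ImageIOError(f"could not decode image {p}: {exc}") from exc
    if raw.size == 0:
        raise ValidationError(f"zero-sized image: {p}")
    if meta is None:
        meta = parse_filename_metadata(p)
    else:
        meta = replace(meta, source_path=str(p))
    return GrayImage(pixels=standardize(raw), meta=meta)


# ---------------------------------------------------------------------------
# flat-field / vignette handling
# ---------------------------------------------------------------------------

def vignette_field(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Radial Gaussian illumination falloff, normalized to unit mean.

    ``strength`` in [0, 1) sets the raw corner-to-center attenuation before
    normalization; 0 yields a perfectly flat field.  Unit-mean normalization
    makes applying the field and then flat-field correcting with it a
    round trip (up to quantization).
    """
    if not 0.0 <= strength < 1.0:
        raise ValidationError(f"vignette strength must be in [0, 1), got {strength}")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (yy - (h - 1) / 2.0) ** 2 + (xx - (w - 1) / 2.0) ** 2
    sigma = min(h, w) / 2.0
    raw = 1.0 - strength * (1.0 - np.exp(-r2 / (2.0 * sigma**2)))
    return raw / raw.mean()


def flatfield_correct(image: GrayImage, reference: GrayImage | np.ndarray) -> GrayImage:
    """Divide out an illumination reference, preserving the mean level.

    ``output = input / (reference / mean(reference))`` clipped to [0, 255].
    A flat reference therefore leaves the image unchanged, and correcting
    the reference by itself yields a constant image at its mean.
    """
    ref = reference.pixels if isinstance(reference, GrayImage) else np.asarray(reference)
    ref = ref.astype(np.float64)
    if ref.shape != image.pixels.shape:
        raise ValidationError(
            f"reference shape {ref.shape} does not match image {image.pixels.shape}"
        )
    if ref.min() <= 0:
        raise ValidationError("flat-field reference must be strictly positive")
    gain = ref / ref.mean()
    corrected = image.pixels.astype(np.float64) / gain
    out = np.clip(np.rint(corrected), 0, 255).astype(np.uint8)
    return GrayImage(pixels=out, meta=image.meta)


# ---------------------------------------------------------------------------
# overlays
# ---------------------------------------------------------------------------

def write_overlay(image: GrayImage, segmentation, out_path: str | Path) -> None:
    """Write an RGB PNG with each instance's boundary drawn in pure green.

    With an empty segmentation the output is the grayscale image replicated
    into RGB, pixel-identical elsewhere.
    """
    from skimage.segmentation import find_boundaries

    rgb = np.stack([image.pixels] * 3, axis=-1)
    for inst in segmentation.instances:
        if inst.mask.shape != image.pixels.shape:
            raise ValidationError("instance mask does not fit the image grid")
        edge = find_boundaries(inst.mask, mode="inner")
        rgb[edge] = (0, 255, 0)
    p = Path(out_path)
    try:
        iio.imwrite(p, rgb.astype(np.uint8), extension=".png")
    except OSError as exc:
        raise ImageIOError(f"could not write overlay {p}: {exc}") from exc


# ---------------------------------------------------------------------------
# run-length-encoded mask text format
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> str:
    """Encode a boolean mask as ``height width; start:length ...`` text.

    Runs are over the row-major flattened mask, 0-based starts.
    """
    m = np.asarray(mask, dtype=bool)
    flat = m.ravel()
    padded = np.concatenate([[False], flat, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    runs = " ".join(f"{s}:{e - s}" for s, e in zip(starts, ends))
    return f"{m.shape[0]} {m.shape[1]}; {runs}"


def rle_decode(text: str) -> np.ndarray:
    """Invert :func:`rle_encode`."""
    head, _, body = text.partition(";")
    h, w = (int(t) for t in head.split())
    flat = np.zeros(h * w, dtype=bool)
    body = body.strip()
    if body:
        for token in body.split():
            start, length = (int(t) for t in token.split(":"))
            flat[start:start + length] = True
    return flat.reshape(h, w)


def write_mask_file(path: str | Path, masks: Sequence[np.ndarray],
                    labels: Sequence[int] | None = None) -> None:
    """Write one RLE line per instance mask: ``<label>| <rle>``."""
    if labels is None:
        labels = list(range(1, len(masks) + 1))
    lines = [f"{lab}| {rle_encode(m)}" for lab, m in zip(labels, masks)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_mask_file(path: str | Path) -> tuple[list[int], list[np.ndarray]]:
    """Read a mask file written by :func:`write_mask_file`."""
    labels: list[int] = []
    masks: list[np.ndarray] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        lab, _, rle = line.partition("|")
        labels.append(int(lab))
        masks.append(rle_decode(rle))
    return labels, masks


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a UTF-8, comma-delimited CSV with header row and '.' decimals."""
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
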