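# Methods

## The optical viability model

Cystic spheroids imaged in brightfield separate into two phenotypes: a
viable spheroid keeps an open lumen whose transparency matches the
surrounding hydrogel, while dying tissue turns opaque and blebbed.  The
scoring model is a straight line through that contrast.  For an instance
mask with mean interior intensity Ī on an image whose background level is
B (both on the 8-bit scale):

    opacity  = max(0, B − Ī)
    V (%)    = clamp(100 − 0.4 · opacity, 0, 100)

- **Scale.** 0.4 percentage points of viability per intensity unit, i.e.
  the full 0–100% range corresponds to a 250-unit drop below background.
  Scores are reported at 0.1% resolution.
- **Background.** The median intensity of all pixels outside every
  instance mask.  The median (not mean) makes the estimate robust to dark
  nanoparticle speckle in noisy matrices; a local-annulus background is
  deliberately out of scope.
- **Clamping.** Interiors brighter than the background clamp to 100%
  (viability cannot exceed 100); opacities beyond 250 units clamp to 0.
- **Sentinel.** An image with no detected instances reports the average
  viability −1.  The sentinel encodes *absence* and is excluded from every
  mean and every distributional statistic; it participates only in the
  presence/absence (ID) confusion analysis.

The per-image average is weighted by instance area, so larger spheroids
carry proportionally more tissue; the unweighted mean is emitted alongside
it in the per-image CSV.  Per-spheroid scores use the plain mean of
interior intensities.  Whether a "weighted average" should weight pixels
or instances is genuinely open; instance-area weighting keeps per-spheroid
scores interpretable, and emitting both image-level means lets users pick.

Live/dead classification is `live ⟺ V > threshold` with threshold 0 by
default (the conventional binary readout).  The threshold is configurable
because coarse raters — humans scoring in 10% steps — call anything below
~10% dead; the F1- and Youden-optimal threshold scans exist to choose such
a cutoff on data.

## Image standardization

Every input is collapsed to one working representation before analysis:
ITU-R 601 luma grayscale (weights 0.299/0.587/0.114), 16-bit integer
images rescaled by their maximum, bilinear resize to 1024×1024, round-
half-even quantization to uint8.  Standardization is idempotent.  Spatial
calibration (µm/px on the standardized grid) never comes from the files —
common instrument exports do not carry a reliable scale — so it is a
required configuration value; the 2.5 µm/px default is a documented
placeholder.  Flat-field correction divides by `reference/mean(reference)`
so a flat reference is the identity and correcting a pure vignette
reference yields its mean.

## Classical segmentation backend

The backend is a deterministic function of (image, parameters):

1. Gaussian smooth (σ = 1 px default).
2. Background level = image median.
3. Boundary evidence = max(darker-than-background response, Sobel
   gradient magnitude / 4).  Both cues are in intensity units; the
   gradient term catches fully transparent spheroids whose only signature
   is the thin dark rim.
4. Hysteresis threshold at 12/30 intensity units, scaled by
   `rim_sensitivity`.
5. Hole filling (captures the bright lumen enclosed by the rim).
6. Connected components; optional distance-transform watershed splitting
   of merged components (off by default — marker-based splitting is
   unreliable for strongly overlapping bodies, which is where a learned
   backend is the right tool).
7. Rim compensation: each component is eroded by `rim_compensation_px`
   (default 3 px = the ~2 px dark rim plus the smoothing halo at σ = 1),
   so the reported mask approximates the lumen interior rather than the
   outer rim edge.  Without this step, rim pixels depress the interior
   mean and bias scores downward, most strongly for small spheroids.
8. Minimum-area filter (`min_area_px`, default 64 at 1024×1024): rejects
   nanoparticle speckle (blob areas ≤ ~50 px² at the generator defaults)
   while keeping small early-day spheroids.

Instance confidence is the constant 1.0 — the backend has no probabilistic
head, and an honest constant keeps the contract uniform across backends.
Masks are plain boolean pixel membership on the row-major 0-based grid.
A registry dispatches named backends through one `segment()` entry point;
the Mask R-CNN adapter and fine-tuning hook validate their inputs and
require the optional torch/torchvision dependencies plus a trained
artifact.

## Synthetic scenes

The generator renders what the scoring model assumes, plus the nuisances
it must survive:

- **Geometry.** Disks with a 2-px darker rim (background − 60) placed
  uniformly at random; radii uniform in `radius_um_range` (default
  100–300 µm at 2.5 µm/px).  Without `allow_overlap`, placement is
  rejection-sampled to disjointness; with it, later instances occlude
  earlier ones in the render while truth masks keep their full extents
  (the 2-D projection of overlapping 3-D bodies).  Truth masks are the
  lumen interior; the rim lies just outside the mask.
- **Intensity.** Interior = clip(B − (100 − V)/0.4, 0, 255): the exact
  inverse of the scoring map, so scoring a noise-free scene with the true
  masks recovers the planted viabilities up to 8-bit quantization
  (≤ 0.25 points).  On the default background of 200 only viabilities in
  [20, 100] are representable without clipping; the default sampling rule
  draws uniformly from that range, while explicit viability lists may go
  below it (the interior then clips at 0 and the planted value is not
  recoverable by scoring — by construction, not by bug).
- **Noise order.** Vignette (radial Gaussian falloff, unit-mean so
  flat-field correction inverts it exactly) → opaque speckle blobs
  (intensity 25, radius 1–4 px, count set by the target area fraction) →
  additive Gaussian noise → quantization.  Ground truth is captured
  before all three.
- **Series.** A longitudinal series shares one spheroid population:
  radii grow geometrically per day, viabilities drop linearly (floored at
  0) after the perturbation day, lineage ids are stable, and per-day
  noise streams derive from `(seed, day)`.  Day labels are 1-based.
  Z-stacks are generated as independent planes with per-plane seeds
  `seed + 1000 + i`; there is no 3-D rendering.

What the generator does *not* emulate — real optics (PSF, depth blur),
irregular and blebbed morphologies, intensity texture inside spheroids,
debris other than circular speckle — bounds what passing tests show: they
validate the algorithmic contracts (scaling, inversion, determinism,
detection of rim/opacity cues), not performance on real tissue, which
requires a trained backend and real annotated data.

## Comparison statistics

- **Instance matching** is greedy one-to-one by descending IoU with a
  0.5 default acceptance threshold — standard practice, deterministic,
  and adequate where double matches are rare.  F1 = 2·tp/(2·tp+fp+fn).
- **EMD** is the 1-D Wasserstein-1 distance between viability samples
  rescaled to [0, 1] (ν/100), via `scipy.stats.wasserstein_distance`; on
  the rescaled axis a δ-point shift moves the statistic by exactly δ/100.
- **Krippendorff's alpha** uses the interval (squared-difference) metric:
  α = 1 − D_o/D_e with the observed disagreement from within-unit value
  pairs weighted 1/(m−1) and the expected disagreement from all pairable
  value pairs.  All-identical data defines α = 1.  The implementation is
  verified against a brute-force coincidence-matrix enumeration in the
  test suite to 1e−12.
- **Threshold scans** evaluate every candidate cutoff at 0 plus the
  midpoints between adjacent distinct scores — a finite grid that covers
  every achievable classification under the strict `score > t` rule —
  and maximize either live-class F1 or Youden's J = sensitivity +
  specificity − 1, resolving ties to the smallest threshold.
- A 10%-step quantization helper emulates coarse expert raters for
  simulation studies.

## Longitudinal analysis

Group viability curves are raw (unnormalized) means over wells with sd
and n per (group, day); sentinel wells are excluded, and a group-day with
only sentinel wells is emitted with n = 0.  Area trends use mean log10
area in µm² (conventional for the spans involved).  Per-z-plane
histograms bin viability in [0,10), …, [90,100] with the top bin closed;
per-plane means use unbinned values.  The default plane layout is 11
planes 40 µm apart around a 320 µm midplane.  Cross-day single-spheroid
tracking is greedy nearest-centroid matching under a 150 µm cap; how to
pair spheroids across imaging days is an analysis choice of this module
(position is the only persistent identifier in label-free data), so
unmatched counts are logged and tracks should be read with that caveat.
Scatter coloring uses a Gaussian KDE with Scott's-rule bandwidth and a
uniform-density fallback for degenerate point sets.

## Numerical and testing choices

- All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; derived streams use fixed offsets, so every artifact
  (images, truth, CSVs, masks) is byte-reproducible for a fixed
  configuration.
- Round-half-even is used wherever floats are quantized to the 8-bit
  grid.
- Problem sizes in the test suite (single scenes per parameter point,
  20 noisy scenes for recovery statistics, 3 wells × 2 groups × 6 days
  for the dose-response run, 11 z-planes, n = 200 for permutation
  scans) were chosen as the smallest sizes at which the quantities being
  checked are stable to well within their asserted tolerances.
- Known limitations: the classical backend's rim compensation is
  calibrated to the 2-px rim / σ = 1 regime and is a tunable for other
  data; heavy overlap is out of the classical backend's reach by design;
  absolute µm² areas depend entirely on the user-supplied calibration.
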