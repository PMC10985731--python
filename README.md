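# spheroscore

Label-free, nondestructive viability quantification of 3D tissue cultures
(spheroids/organoids) from brightfield microscopy images.

Standard viability readouts for 3D cultures — colorimetric dyes,
fluorescent probes, or ATP-luminescence assays such as CellTiter-Glo —
either require labeling or destroy the sample, which rules out following
the *same* spheroids through a multi-day drug-response experiment.  Cystic
spheroids, however, encode their state optically: a healthy spheroid has
an open, transparent lumen that transmits light like the surrounding gel,
while dead material is opaque and dark.  `spheroscore` turns that
observation into a quantitative pipeline for experimentalists running
well-plate imaging assays:

1. **Standardize** any TIFF/PNG/JPG export to a 1024×1024 8-bit grayscale
   frame (ITU-R 601 luma, bilinear resize), with optional flat-field
   (vignette) correction.
2. **Segment** each spheroid instance through a pluggable backend.  The
   shipped classical backend is deterministic (boundary evidence →
   hysteresis → lumen fill → rim compensation); an adapter for a
   fine-tuned Mask R-CNN backend is provided for users with the optional
   torch dependency and a trained artifact.
3. **Score** each spheroid's viability from mean interior intensity
   relative to the image background:

   V = clamp(100 − 0.4 · max(0, B − Ī), 0, 100)

   where *B* is the median background intensity, *Ī* the mean intensity
   inside the instance mask, and 0.4 %/unit the per-pixel scale (a full
   0→100% range spans a 250-unit drop on the 8-bit scale).  Scores are
   reported at 0.1% resolution; an image with no spheroids reports the
   sentinel value **−1**.
4. **Compare and aggregate**: detection (ID) and live/dead (LD) F1,
   mask IoU, Earth Mover's distance and Krippendorff's interval alpha
   between raters, Pearson correlation matrices, optimal live/dead
   cutoffs by F1 or Youden's J, dose-response time series, mean log10
   area trends, cross-day spheroid tracking, and per-z-plane viability
   histograms.

A seeded synthetic scene generator (`spheroscore.synth`) renders cystic
spheroids with pixel-exact ground-truth masks and viabilities — including
overlapping instances, nanoparticle speckle, vignetting, and multi-day
growth/perturbation series — so every stage of the pipeline is testable
without microscope data.

## Worked example

```python
from spheroscore import (Calibration, SceneSpec, generate_scene, segment,
                         summarize_image)
from spheroscore.evaluation import match_instances

spec = SceneSpec(n_spheroids=5, radius_um_range=(80.0, 220.0),
                 speckle_density=0.03, gaussian_noise_sigma=4.0, seed=11)
image, truth = generate_scene(spec)
result = segment(image, backend="classical")
summary, records = summarize_image(image, result, Calibration(microns_per_pixel=2.5))

print(f"spheroids detected: {summary.n_spheroids}")
print(f"well average viability (area-weighted): {summary.avg_viability:.1f}%")
pairs, counts = match_instances(result, truth)
for pred_idx, truth_idx, iou in pairs:
    rec = records[pred_idx]
    print(f"  spheroid {rec.label}: viability {rec.viability_pct:.1f}% "
          f"(planted {truth.viabilities[truth_idx]:.1f}%), "
          f"radius {rec.radius_um:.0f} um, IoU {iou:.2f}")
```

prints

```
spheroids detected: 6
well average viability (area-weighted): 48.1%
  spheroid 1: viability 30.7% (planted 30.4%), radius 165 um, IoU 0.99
  spheroid 3: viability 26.3% (planted 25.6%), radius 151 um, IoU 0.98
  spheroid 5: viability 69.1% (planted 69.8%), radius 101 um, IoU 0.98
  spheroid 2: viability 92.1% (planted 94.3%), radius 99 um, IoU 0.97
  spheroid 4: viability 92.1% (planted 95.9%), radius 86 um, IoU 0.95
```

All five planted spheroids are recovered with IoU ≥ 0.95 and scores within
~2.5 points of the planted viabilities despite speckle and sensor noise;
the sixth "detection" is a cluster of nanoparticle speckle large enough to
pass the minimum-area filter — exactly the failure mode the noisy-matrix
robustness statistics are there to quantify.

## Command line

```bash
spheroscore simulate --spec scene.toml --out sim/          # images + truth
spheroscore analyze  --input sim/ --out run/ --mpp 2.5     # CSVs + overlays
spheroscore evaluate --pred run/images.csv --ref sim/truth_images.csv \
    --pred-masks run/masks --truth-masks sim/masks --out metrics.csv
```

`analyze` emits a per-spheroid CSV, a per-image CSV (with the −1
sentinel), green-outline overlay PNGs, run-length-encoded mask text files,
and a run log; all outputs are byte-reproducible for a fixed
configuration.  Exit codes: 0 success, 1 validation/config, 2 I/O,
3 internal.

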