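# retoct

Synthetic-phantom-driven analysis pipeline for preclinical retinal OCT:

- **phantom** — curved 10-layer retina simulator with an optic-nerve-head pit,
  multiplicative gamma speckle, vessel shadows, per-B-scan axial jitter, and
  longitudinal paired-eye cohorts with known injected per-layer thickness
  effects (ground truth retained for every volume).
- **preprocess** — axial motion correction (adjacent B-scan registration by
  normalized cross-correlation, polynomial detrending that preserves retinal
  curvature) and 3D bounded-variation speckle smoothing with SNR/CNR reporting.
- **segment** — a small trainable U-Net (pure NumPy, CPU-friendly) with the
  full transfer-learning protocol: frozen-head stage, fine-tuning with affine
  augmentation, and a pseudo-labeling round; optional cascaded second stage.
- **surfaces** — dense labels → ordered boundary surfaces (median inpainting,
  isotonic ordering enforcement), isotropic lateral resampling, and
  nearest-neighbor (k = 1) shortest-distance thickness maps in physical µm.
- **roi** — full / central / peripheral annular masks centred on the detected
  optic nerve head, with a wide exclusion margin, and regional mean thickness.
- **stats** — per (layer × region × day) paired t-tests between injected and
  control eyes, Benjamini–Hochberg FDR (q = 0.1, per-panel families),
  percent-change summaries, tidy CSV results.

Everything downstream is exercisable end-to-end on simulated cohorts; a
ground-truth-label mode bypasses the trained model so geometry and statistics
do not depend on training stochasticity.

## CLI

```sh
# simulate a 9-subject paired-eye cohort with the packaged effect profile
retoct simulate --effects paper --n-subjects 9 --seed 1 --out cohort/

# motion-correct (and optionally denoise for visualization) one volume
retoct preprocess --in vol.tiff --out corrected.tiff --poly-order 2 --max-shift 12 --denoise

# train the segmentation model on two labeled volumes + pseudo-labeling
retoct train --cohort cohort/manifest.csv --labeled "0:control:0,1:control:0" --out model.npz

# predict labels / compute thickness tables / run statistics
retoct segment --model model.npz --in vol.tiff --out labels.tiff
retoct thickness --labels labels.tiff --out thickness.csv
retoct analyze --thickness-table thickness.csv --out results.csv --fdr-q 0.1

# or the whole pipeline from a manifest (ground-truth-label mode if label
# paths are present, model mode with --model)
retoct run --manifest cohort/manifest.csv --out results/
```

Volumes are multi-page TIFF or NIfTI with voxel spacing in the metadata;
surfaces are NPZ containers with a JSON header; tables are CSV.

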