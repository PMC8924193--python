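# mxifseg

Weakly supervised single-cell segmentation for two-channel multiplexed
immunofluorescence (MxIF) images: a nuclear channel (DAPI) plus a membrane
channel (e.g. Na⁺K⁺ATPase).

The package implements an end-to-end desk-scale pipeline:

- **`raster_core`** — image data model (8/16-bit rasters, DAPI-MEM-DAPI
  stacked color images), TIFF/PNG I/O, 16→8-bit conversion, 2× nearest
  upscaling, per-channel normalization, and the training-time augmentation
  operators (flip / Gaussian blur σ 5.0 / intensity scale 0.8–1.5 /
  right-angle rotations).
- **`nuclear_weak_labeler`** — classical nuclear segmentation (exhaustive
  Otsu threshold → hole filling → distance-transform seeding → deterministic
  priority-flood watershed), the three-class
  boundary/interior/background encoding and its inverse, and application of
  recorded human edit overlays (split polylines, removal contours).
- **`semantic_bootstrap`** — a trainable three-class segmenter (small numpy
  encoder–decoder with skip connections) and the three-round recursive
  bootstrap: classic labels + edits → model + edits → prediction-only.
- **`cell_weak_labeler`** — cell weak labels from nuclear seeds: 3×3 marker
  erosion, unmasked membrane watershed, ≥1400 px background size filter,
  white/black/grey cell maps, per-cell mask stacks.
- **`instance_seg_harness`** — the two-stage domain-adaptation protocol
  (heads-only then all-layers fine-tuning, weak-label stage before
  manual-label stage) over a pluggable instance-segmentation backend, with a
  CPU-sized reference backend; inference back to instance label maps.
- **`eval_metrics`** — Dice, boundary Hausdorff, and size-weighted
  bidirectional object-Dice / object-Hausdorff with maximal-overlap
  matching, plus multi-observer pairwise agreement reports.
- **`synthetic_mxif`** — synthetic ROI generator (packed cells, nuclei,
  membrane ridges with controllable breaks/noise), a ground-truth "oracle"
  edit provider, and label degradation for ablations.
- **`cli_profiler`** — per-cell measurement tables (centroid, area in px and
  µm², per-channel mean intensity, containing nucleus) and the `mxifseg` CLI.

The heavy region-proposal backend (Mask R-CNN / ResNet-101) used for the
original full-scale experiments is out of scope here; the harness exposes the
backend contract and ships a small reference backend so the training protocol
is exercisable on one CPU.

## Test

```sh
python -m pytest -q tests/
```

The suite includes independent brute-force oracles (priority-flood watershed,
exhaustive Otsu, per-definition object metrics) that optimized code paths are
checked against, and `tests/test_acceptance.py` with one test per acceptance
criterion. The full run takes about a minute on one CPU.

## CLI

```sh
mxifseg simulate  --seed 1 --frame 128 128 --n-cells 32 --out roi/
mxifseg weaklabel --dapi roi/dapi.tif --mem roi/mem.tif --out weak/
mxifseg bootstrap --roi-dirs roi1/ --roi-dirs roi2/ --roi-dirs roi3/ --out boot/
mxifseg train     --stage1-rois weakroi/ --stage2-rois manualroi/ --out model/
mxifseg segment   --backend model/backend.npz --dapi roi/dapi.tif --mem roi/mem.tif --out pred/
mxifseg evaluate  --pred-dir pred/ --truth-dir truth/ --out report.csv
mxifseg profile   --cells cells.tif --channel CD3 cd3.tif --out table.csv
```

Every command writes a `run_manifest.json` recording the tool version, the
command and its parameters for reproducibility. See `--help` on any
subcommand for the full flag list.

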