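# polcontrast

Signed degree-of-polarization (DOP) imaging and tumor/background contrast
statistics for reflection-mode polarimetry, with a fully synthetic test bench.

The package implements:

- **`polcontrast.polarimetry`** — Stokes components from analyzed
  intensities; **signed circular DOP** (`sign(S3_in) · (I_R−I_L)/(I_R+I_L)`,
  negative = helicity flipped), **signed linear DOP** (two-experiment
  definition, negative = co-linear dominance); per-pixel 4×4 Mueller-matrix
  reconstruction by exact inversion of a 16-measurement generator/analyzer
  design; beam-splitter correction; total-DOP magnitude
  `(|DOLP|+|DOCP|)/2`.
- **`polcontrast.segmentation`** — tumor masking by fluorescence threshold
  (fraction of max, boundary-inclusive), N-pixel-thick outline extraction
  (Chebyshev erosion, default 5 px), fiducial-based rigid/similarity/affine
  registration and nearest-neighbour mask warping between the fluorescence
  and polarimetry frames.
- **`polcontrast.contrast`** — per-class unit-area histograms and their
  overlapping coefficient; pixel-level ROC over a −0.95…+0.95 sweep in
  0.05 steps (positives strictly above threshold) with trapezoidal AUC and a
  seeded stratified bootstrap 95 % CI; per-class mean/SD summaries.
  Because a class that is *more negative* drives the literal signed AUC
  below 0.5, both the signed AUC and a |value| variant are reported.
- **`polcontrast.synthetic`** — seeded, bit-reproducible synthetic scenes:
  two-class truncated-normal DOP fields realized exactly in intensity
  frames, a co-located fluorescence blob under a known similarity
  transform, fiducial disks in both frames, noise models, a forward Mueller
  simulator, and closed-form AUC/overlap expectations used as oracles.
- **`polcontrast.pipeline` / `polcontrast.cli`** — an end-to-end pipeline
  with per-stage logging, stage-named failure exit codes, CSV/JSON outputs
  and report figures.

## CLI

```bash
# full synthetic run: frames + fluorescence + fiducials -> DOP/Mueller ->
# mask/registration -> histograms, overlap, ROC/AUC/CI, summaries, figures
polcontrast run-all --out out/demo --seed 1

# individual stages
polcontrast simulate --out out/sim --seed 1
polcontrast dop      --frames out/sim/frames --out out/dop
polcontrast mueller  --frames out/sim/mueller_frames --out out/mm
polcontrast segment  --fluorescence out/sim/fluorescence.tif --out out/seg
polcontrast register --fiducials out/sim/fiducials.csv \
    --mask out/seg/mask_fluorescence.png --outline out/seg/outline_fluorescence.png \
    --rows 256 --cols 256 --out out/reg
polcontrast contrast --docp out/dop/docp.tif --dolp out/dop/dolp.tif \
    --mask out/reg/mask_polarimetry.png --out out/contrast
polcontrast report out/demo
```

A YAML config (same keys as `polcontrast.pipeline.RunConfig`) can be passed
with `--config`; explicit CLI flags win over config-file values. All
randomness derives from the single run seed.

External data are accepted as single-page TIFFs with a JSON manifest mapping
files to (incident, analyzed) state pairs — or one multi-page TIFF with the
page order declared in the manifest — plus a fluorescence TIFF/PNG and a
fiducial CSV (`frame,point_id,row,col`).

## Conventions

- Stokes: `S1 = I_H − I_V`, `S2 = I_+45 − I_−45`, `S3 = I_R − I_L`,
  right-circular positive.
- Coordinates: 0-based `(row, col)`, origin top-left.
- Signed linear DOP can mathematically leave [−1, 1] when both experiments
  pull the same way (an ideal mirror gives −2); such pixels are flagged,
  never clamped.
- Pixels whose total intensity falls below a configurable floor are marked
  invalid and excluded from all statistics.
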