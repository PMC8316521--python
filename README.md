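# cumulantscope

A toolkit for correlative fluctuation super-resolution imaging and
scanning-ion-conductance topography, built around fully synthetic, ground-truth
data so every stage is testable offline:

- **synth** — blinking point emitters (two-state telegraph statistics) imaged
  through a Gaussian PSF onto a pixel grid with Poisson shot noise and read
  noise, as single-plane movies or 8-plane defocus series (350 nm spacing);
  plus cell-like topographies (dome + microvilli bumps + filopodia ridges)
  with full feature ground truth.
- **preproc** — frame exclusion, single-exponential bleaching-lifetime fits,
  and drift correction by cross-correlating 2nd-order cumulant images of
  movie sub-sequences.
- **sofi** — 2nd–4th order auto-/cross-cumulant images and volumes on the
  n-fold refined virtual-pixel grid, with distance-factor flattening. Order-n
  processing narrows the effective PSF by √n. Multiplane input with P
  physical planes yields n(P−1)+1 output planes (8 planes at order 3 → 22
  planes spaced 116 nm).
- **postproc** — linearization (nth-root magnitude) and Lucy–Richardson
  deconvolution with a Gaussian PSF model.
- **decorr** — single-image resolution estimation by decorrelation analysis
  (masked spectral correlation over a family of high-pass filters).
- **sicm** — hopping-mode pipette scan simulation with an invertible
  current–distance law `I/I∞ = 1/(1 + c_s·r_p/z)` and a 99% current setpoint,
  plus plane leveling and band-pass filtering of height maps. The aperture
  footprint reproduces the ~3·r_p lateral resolution rule.
- **coreg** — control-point affine registration, bilinear warping,
  cross-section profile extraction, Pearson correlation of height/intensity
  profiles, and Welch two-sided t-tests between section groups
  (Fisher-z transformed by default).
- **livecell** — interleaved scan/fluorescence acquisition bookkeeping
  (e.g. 300-frame stacks at 50 ms, first 50 frames dropped → 12.5 s temporal
  resolution per reconstructed frame) and synthetic time-lapse runs.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact plane-count /
timing arithmetic plus property-based checks: √n PSF narrowing, telegraph
cumulant closed forms, decorrelation resolution recovery, scan fidelity,
registration closure, correlation statistics).

## CLI

Everything is reachable through one umbrella command:

```sh
cumulantscope simulate-blinks --seed 1 --frames 2000 --out movie.tif
cumulantscope sofi2d movie.tif --order 4 --out sofi.tif
cumulantscope postprocess sofi.tif --iters 20 --out final.tif
cumulantscope resolution final.tif --pixel-size 26.75

cumulantscope simulate-topo --seed 2 --out topo.tif
cumulantscope sicm-scan topo.tif --radius 50 --out height.tif
cumulantscope sicm-level height.tif --out leveled.tif
cumulantscope sicm-bandpass leveled.tif --low-cut 2000 --high-cut 250 --out mv.tif

cumulantscope register points.csv --out affine.json
cumulantscope profiles height.tif sofi.tif sections.csv --out profiles.csv
cumulantscope correlate profiles.csv

cumulantscope timelapse --cycles 3 --seed 4 --out timelapse/
cumulantscope run            # full demo pipeline from the shipped YAML config
```

Image stacks are multi-page TIFF with a JSON sidecar carrying all metadata;
ground truth, control points, sections and drift tracks are CSV; height maps
also export as plain-text matrices.

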