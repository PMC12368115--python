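# dhpsf — double-helix PSF 3D single-molecule localisation

The double-helix point spread function (DH-PSF) encodes an emitter's axial
position in the orientation of two lateral lobes: as the emitter moves
through focus, the line joining the lobes rotates.  `dhpsf` turns tables of
independently fitted 2D lobes into 3D single-molecule localisations and
provides everything around that step needed for a quantitative SMLM
workflow:

* **Calibration** — from a single-bead z-stack, fit polynomial curves (in a
  numerically stable rescaled basis, default degree 15) relating the
  rotation angle θ to z, the midpoint wobble (dx, dy), the interlobe
  distance d and the lobe intensity ratio r, with diagnostics and angular
  range restriction (the angle-to-z map is only single-valued over < 180°).
* **Localisation** — per frame, pair lobes via the pairwise Euclidean
  distance matrix (greedy minimal-deviation matching within an expected
  distance range), read z off z(θ), correct the midpoint by the wobble
  curves, and filter pairs whose interlobe distance or intensity ratio
  deviates from the calibration by more than a user tolerance.
* **Detection** — a spot detector (Gaussian-smoothed local maxima over a
  robust threshold) with pixel-integrated 2D Gaussian fitting and a
  deflation refit that removes the bias of a neighbouring lobe's tail.
* **Simulation** — a parametric rotating two-Gaussian-lobe PSF with exact
  ground truth: 119 × 33.3 nm calibration stacks spanning ~4 µm, test
  stacks with configurable density and signal-to-noise (S/N = mean
  brightest pixel / noise sd), intensity jitter U(1, 1.2), and Gaussian
  background noise normalised to mean level 50.
* **Benchmarking** — one-to-one ground-truth matching and the standard
  metrics: precision TP/(TP+FP), sensitivity TP/(TP+FN), Jaccard index
  TP/(TP+FP+FN), localisation-accuracy distributions, sensitivity-vs-z.
* **Post-processing** — cross-correlation and fiducial drift correction,
  transitive blinking grouping, and Fourier shell correlation (FSC)
  resolution estimation (1/7 threshold), including a block-wise variant.

It is aimed at microscopists analysing DH-PSF SMLM data and at method
developers who need a controlled simulator with known ground truth.

## Worked example

`examples/01_calibration.py` builds a calibration from a simulated
noiseless bead stack:

```
calibration stack: 119 frames, z from -2000.0 to 1929.4 nm
detected 238 lobes (2.0 per frame)
usable angle range: 5.0 to 172.0 degrees
   z residual rms: 0.00315
  dx residual rms: 0.0717
  dy residual rms: 0.0801
   d residual rms: 0.2
   r residual rms: 0.0011
z(theta) strictly monotonic: True
```

Two lobes per frame pair into one angle measurement each; the z residual of
3 pm shows the degree-15 polynomial captures the (linear) angle-to-z law
essentially exactly, and the monotonicity check confirms the angle range is
usable.  `examples/03_benchmark.py` then scores the full pipeline against
ground truth (100 frames per condition, restricted axial window):

```
restricted z window: -1607 to 1536 nm
S/N 23.0, 10 molecules/frame: precision 0.998, sensitivity 0.990, Jaccard 0.988, median 3D error 11.7 nm
S/N  5.8, 15 molecules/frame: precision 0.982, sensitivity 0.975, Jaccard 0.958, median 3D error 46.2 nm
```

At high S/N essentially every molecule is recovered with ~12 nm 3D
accuracy; at the hardest condition (low S/N, high density) the Jaccard
index stays above 0.95 while the accuracy degrades to ~46 nm, dominated by
photon noise in the lobe fits.  The other examples demonstrate
localisation + ViSP export, drift correction + blinking grouping, and FSC
resolution.

A thin CLI mirrors the library:

```bash
dhpsf simulate --mode calibration --out cal.tif
dhpsf detect --in cal.tif --out cal_peaks.csv
dhpsf calibrate --peaks cal_peaks.csv --zstep 33.3 --out model.json --plots out/
dhpsf unmix --peaks peaks.csv --model model.json --out locs.csv --visp locs.3d
dhpsf evaluate --detected locs.csv --truth truth.csv
dhpsf drift|group|fsc ...
```

## Notes

* Coordinates are 0-based pixels (x = column, y = row); physical positions
  are coordinate × pixel size (supplied by the user, not read from TIFF
  tags).  Localisation tables are in nm.
* The ViSP export is headerless tab-separated `x y z intensity frame`.
* See `docs/methods.md` for the model, parameter defaults and their
  rationale, numerical choices, and known limitations.
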