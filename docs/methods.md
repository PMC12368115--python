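# Methods

## The localisation model

A double-helix PSF images a point emitter as two lobes whose connecting
line rotates with the emitter's axial position z.  Given per-frame 2D lobe
positions (from the built-in detector or an external fitter), localisation
proceeds in two stages.

**Calibration.**  A single fluorescent bead is stepped through known axial
positions (default 119 steps of 33.3 nm, spanning ~3.93 µm).  Every usable
frame contributes exactly two lobes; frames with any other number of peaks
are skipped with a warning.  From each pair we measure the rotation angle
θ = atan2(Δy, Δx) folded into [0°, 180°), the midpoint, the interlobe
distance d and the intensity ratio r, where r is the intensity of the
smaller-x lobe (ties broken by smaller y) divided by the other.  Five
polynomial curves are then least-squares fitted against θ: z(θ), the
midpoint shift dx(θ), dy(θ) relative to the first usable frame (the
"wobble" caused by optical imperfections), d(θ) and r(θ).  Fits use
numpy's orthogonal-series formulation with θ internally rescaled to
[−1, 1]; a raw monomial basis at degree 15 would be badly conditioned.
The usable angle interval is the span of the retained calibration angles.
Because the angle-to-z map is single-valued only over less than 180° of
rotation, a non-monotonic θ-versus-frame sequence is rejected with a
pointer to `frame_range` trimming, and diagnostics report per-curve
residuals, monotonicity flags and a suggested angular trim.

**Localisation.**  For each frame of the experimental peak list the
pairwise Euclidean distance matrix is computed and peak pairs whose
separation lies in an expected range become candidates.  The range defaults
to [0.8 · min d(θ), 1.2 · max d(θ)], anchored to the calibration rather
than hard-coded.  Conflicts are resolved greedily: candidates are sorted by
|d − centre of range| ascending (deterministic index tie-break) and
accepted only if neither peak is already used.  Unpaired peaks are treated
as noise.  Each accepted pair yields z = z(θ); the xy position is the
lobe midpoint minus (dx(θ), dy(θ)); the intensity is the summed lobe
intensity.  Pairs whose angle falls outside the calibrated interval cannot
be assigned a z and are rejected (`angle_range`).  Remaining pairs are
filtered against the calibration: reject if |d_obs − d(θ)| > tol_d · d(θ),
or if |log r_obs − log r(θ)| > log(1 + tol_r).  The ratio filter operates
on the log scale so that deviations by a factor f and 1/f are treated
symmetrically.  Library defaults are tol_d = tol_r = 0.25; both are
user-facing knobs, because the appropriate width scales with the
photometric noise of the data (see "Benchmark analysis profile").

Greedy pairing and greedy ground-truth matching are used instead of
optimal assignment for speed and determinism; the test suite quantifies
the gap against a brute-force/`linear_sum_assignment` oracle (agreement
≥ 95% on random instances with realistic error scales).

## Spot detection

Candidates are local maxima of the Gaussian-smoothed frame (σ = 1.1 px)
above background + T·σ_noise, with background the frame median and
σ_noise = 1.4826 × MAD of the smoothed frame (robust to sparse bright
spots); maxima closer than 2 px keep only the brighter.  Default T = 4,
which keeps spurious candidates to about one per 512² frame of pure noise
while detecting lobes down to the lowest benchmarked S/N.  Each candidate
is refined by unweighted least squares on a 9 × 9 window with a
pixel-integrated circular 2D Gaussian (flux, centre, width, offset); the
reported intensity is the integrated flux (equal to 2π·A·σ² of the
equivalent sampled Gaussian).  Fits are rejected for non-convergence,
vanishing amplitude, width outside [0.5, 3] × the prior width, centre
drifting out of the window, or a window clipped by the frame border;
near-duplicate fits within 1 px of a brighter accepted fit are dropped.

Because the partner lobe of a DH-PSF sits only ~5 px away, its tail inside
the fit window biases a naive single-spot fit (up to ~16% on the intensity
ratio for the default geometry, even without noise).  `detect_frame`
therefore performs one deflation pass: after the first fits, each spot is
refitted on the frame with the fitted models of all other accepted spots
subtracted.  This reduces the noiseless ratio bias below 1% and leaves the
5-parameter window-fit contract unchanged.

## The synthetic-data generator

The simulator replaces a phase-retrieved experimental PSF with an analytic
rotating two-Gaussian-lobe model — the same two-lobe Gaussian description
that simpler DH-PSF fitters assume — so that ground truth is exact and
every calibration law is known in closed form:

* θ(z) linear: θ0 = 5° at z_min, total span 170° (< 180° to keep the
  angle-to-z map single-valued) over z ∈ [−2000, 2000] nm;
* d(z) = d0 + d2·z² with d0 = 1050 nm and d2 = 6.5625 × 10⁻⁵ nm⁻¹
  (≈ +25% at the range extremes), so lobes stay resolvable at 210 nm
  pixels with σ = 1.1 px lobes;
* r(z) = 1 + 10⁻⁴·z (0.8 → 1.2 across the range), attached to the
  smaller-x lobe so the measured ratio curve is continuous in θ;
* sinusoidal midpoint wobble with 30 / 20 nm amplitude in x / y, zero at
  z_min so the first calibration frame defines the wobble origin.

Lobes are rendered as pixel-integrated Gaussians (erf-based), so the total
added flux equals the molecule intensity up to edge truncation.  Test
datasets place molecules uniformly (sub-pixel) over the canvas interior —
default 512 × 512 px, the sensor size of the EMCCD the default geometry
mimics — with a border margin of 3σ + d_max/2 + 1 px so whole PSFs stay
on-canvas, z uniform over a configurable window, and per-molecule
intensity jitter U(1, 1.2).  Gaussian noise is added with a standard
deviation solved from the requested S/N under the definition
S/N = (mean brightest rendered pixel across molecules) / σ_noise, and the
stack is affinely renormalised so the mean background level is 50 counts
(which leaves the S/N invariant).  Everything is bit-reproducible for a
fixed seed.

What the generator does **not** emulate: diffraction side-lobes and
aberrations of real phase masks, Poisson/EMCCD excess noise, sCMOS
pixel-dependent noise, field-dependent PSF variation, or rotation angles
beyond the calibrated range re-entering from the other side.  Passing
benchmarks on this generator therefore demonstrates the correctness and
noise behaviour of the pairing/calibration logic, not robustness to PSF
model mismatch.

## Benchmark pipeline and analysis profile

The benchmark workflow (`pipeline.py`) builds the calibration from a
simulated noiseless bead stack (z of frame i = z_min + i · 33.3 nm, so
detected z shares the ground-truth axis), then simulates test stacks with
molecule z drawn over the calibrated span, and scores detections against
truth with greedy per-frame matching at 250 nm lateral / 500 nm axial
tolerance (recorded in every report).  The "restricted" axial window is
the central 80% of the calibrated span, mirroring the usual exclusion of
near-horizontal PSF extremes where analytic DH fitters degrade.

Filter tolerances for benchmarking are fixed a priori by noise
propagation at the lowest benchmarked S/N (5.8): the robust sd of the
measured log-ratio residual is ≈ 0.21 (the fitted flux inherits variance
from the offset and width degeneracies of the window fit), so
tol_r = e^(3·0.21) − 1 ≈ 0.90 gives 3σ coverage; the relative distance
residual sd is ≈ 0.034, so tol_d = 0.3 is ample.  At high S/N the wide
ratio tolerance costs nothing: false pairs must already survive the
distance-range gate, the angle-range cut and the distance filter.

Problem sizes: the scenario suite uses 500-frame stacks (7,500 molecules
at the hardest condition) and the full-grid scan 300 frames per cell;
these sizes give Jaccard estimates with sampling error well below the
margins being tested while keeping a full run in the minutes range on one
CPU.

## Post-processing

**Drift.**  Lateral drift is estimated by rendering temporal blocks as 2D
histograms (default 50 nm bins), FFT cross-correlating each block against
the first non-empty block, refining the correlation peak with a 1D
parabolic fit per axis, and linearly interpolating shifts between block
centres when correcting per frame.  Empty blocks inherit the previous
shift with a warning.  The fiducial mode subtracts a bead track (mean
centred, gaps linearly interpolated) frame by frame.  Only lateral drift
is corrected.

**Blinking.**  Localisations are linked when their lateral distance is
< dxy_max (default 150 nm; optionally |Δz| < dz_max) and their frame
difference ≤ max_gap (default 50).  Linking is transitive — connected
components merge into one molecule with unweighted mean coordinates,
summed intensity, first frame and a multiplicity count.  Transitive
closure (rather than pairwise-to-seed linking) was chosen because it is
order-independent; note that in extremely dense data it can percolate, so
the linking radius should stay below the typical nearest-neighbour
distance.  Coordinates are averaged without intensity weighting.

**FSC.**  The localisations are randomly half-split (seeded), each half
voxelised into a cube (default 5 nm voxels, zero-padded to a common fast
FFT size) and blurred with a 3D Gaussian of σ = (3, 3, 5) voxels — the
blur argument is interpreted as a sigma matching the expected 3D
localisation precision, not a kernel size.  The correlation of the two
Fourier transforms is averaged over spherical shells one frequency bin
wide, and the resolution is 1/frequency at the first descent through the
1/7 threshold (linearly interpolated between shells); a curve that never
descends reports the Nyquist limit 2 × voxel.  The block-wise variant
splits the volume into cubes (default 1 µm) and analyses blocks holding
more than a minimum number of localisations (default 1000), reporting the
per-block map and mean.

## Numerical choices and degenerate inputs

* Degree-15 calibration fits need ≥ degree + 2 usable frames; the degree
  is a knob (sensible range 3–15) since high degrees overfit noisy
  calibrations.
* Coincident lobes (d = 0) are an error in feature extraction; empty
  frames, frames with a single peak, and all-rejected tables flow through
  as empty results (with warnings where information is lost).
* Matching, pairing and grouping are deterministic under fixed inputs;
  ties break by index.
* An S/N request of infinity yields a noiseless stack with the background
  still normalised to 50.
* Undefined metrics (zero denominators) are returned as NaN rather than
  raised.

## Scope and limitations

Single-bead calibrations only (multi-bead auto-pairing is out of scope);
polynomial calibration only (no splines); symmetric Gaussian lobe fits (no
elliptical or maximum-likelihood fitting); no multi-emitter deconvolution
of overlapping DH-PSFs — density robustness comes from pairing, not
unmixing overlapping lobe images; no axial drift correction; no GPU path.
Rotation angles beyond the calibrated interval are excluded rather than
disambiguated, so molecules outside the calibrated axial range are
unrecoverable by design.
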