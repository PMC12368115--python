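"""End-to-end convenience layer: simulate -> detect -> calibrate -> unmix -> evaluate.

This module wires the individual modules into the benchmark workflow used
throughout the examples and the acceptance script: build a calibration from
a simulated noiseless 119-step / 33.3 nm bead stack, render a multi-molecule
test dataset at a requested S/N and density, run detection and lobe
pairing, and score the result against the ground truth.

Analysis profile
----------------
Detection uses the default detector settings.  The pairing range is anchored
to the calibration distance curve ([0.8 min d, 1.2 max d]).  The benchmark
filter tolerances are ``tol_d = 0.3`` and ``tol_r = 0.90``, calibrated to
3 sigma of the measured feature noise at the lowest benchmarked S/N (5.8):
there the robust standard deviation of the log intensity-ratio residual is
~0.21 (the fitted flux inherits extra variance from the local-offset and
width degeneracies of the window fit), so ``log(1 + tol_r) ~ 0.64`` gives
3-sigma coverage; the relative interlobe-distance residual sd is ~0.034,
so ``tol_d = 0.3`` is ample.  Matching tolerances are 250 nm laterally,
500 nm axially.

Molecule z positions are drawn over the calibrated axial span
(z_min .. z_min + 118 * 33.3 nm); the restricted z-window used for
"optimal-range" scoring is the central 80% of that span, mirroring the
exclusion of near-horizontal PSF extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calibrate import CalibrationModel, build_calibration
from .detect import DetectionParams, detect_stack
from .evaluate import MatchReport, Metrics, accuracy_stats, filter_z_window, match, metrics
from .simulate import GeneratorModel, SimulationScene, simulate_calibration, simulate_dataset
from .unmix import UnmixParams, unmix_stack

CAL_N_STEPS = 119
CAL_STEP_NM = 33.3

BENCH_TOL_D = 0.30
BENCH_TOL_R = 0.90
BENCH_TOL_XY_NM = 250.0
BENCH_TOL_Z_NM = 500.0


def default_generator() -> GeneratorModel:
    """The 210 nm-pixel, ~4 um-range generator used for benchmarks."""
    return GeneratorModel()


def calibrated_z_span(gen: GeneratorModel, n_steps: int = CAL_N_STEPS,
                      step_nm: float = CAL_STEP_NM) -> tuple:
    z0 = gen.z_range_nm[0]
    return (z0, z0 + (n_steps - 1) * step_nm)


def restricted_z_window(gen: GeneratorModel, fraction: float = 0.8) -> tuple:
    """Central ``fraction`` of the calibrated axial span."""
    lo, hi = calibrated_z_span(gen)
    pad = 0.5 * (1.0 - fraction) * (hi - lo)
    return (lo + pad, hi - pad)


def build_reference_calibration(gen: GeneratorModel, degree: int = 15,
                                detect_params: DetectionParams | None = None
                                ) -> CalibrationModel:
    """Calibration model fitted to a simulated noiseless bead z-stack."""
    stack, _zs = simulate_calibration(gen, n_steps=CAL_N_STEPS, step_nm=CAL_STEP_NM)
    peaks = detect_stack(stack, detect_params or DetectionParams())
    return build_calibration(
        peaks, z_step_nm=CAL_STEP_NM, pixel_size_nm=gen.pixel_size_nm,
        degree=degree, z0_nm=gen.z_range_nm[0],
    )


def benchmark_unmix_params(model: CalibrationModel) -> UnmixParams:
    return UnmixParams.from_model(model, tol_d=BENCH_TOL_D, tol_r=BENCH_TOL_R)


@dataclass
class BenchmarkResult:
    """Scored outcome of one simulated benchmark run."""

    metrics: Metrics
    report: MatchReport
    accuracy: dict
    scene: SimulationScene
    locs: pd.DataFrame
    z_window: tuple | None


def run_benchmark(gen: GeneratorModel, model: CalibrationModel,
                  n_frames: int, per_frame: int, snr: float, seed: int,
                  z_window: tuple | None = None,
                  canvas_px: tuple = (512, 512),
                  detect_params: DetectionParams | None = None,
                  unmix_params: UnmixParams | None = None,
                  tol_xy_nm: float = BENCH_TOL_XY_NM,
                  tol_z_nm: float = BENCH_TOL_Z_NM) -> BenchmarkResult:
    """Simulate a test stack and score the full pipeline against truth.

    ``z_window`` restricts the evaluation (both truths and detections) to
    an axial window; ``None`` evaluates the full range.
    """
    stack, scene = simulate_dataset(
        gen, n_frames=n_frames, per_frame=per_frame, snr_target=snr,
        seed=seed, canvas_px=canvas_px, z_window=calibrated_z_span(gen),
    )
    peaks = detect_stack(stack, detect_params or DetectionParams())
    locs = unmix_stack(peaks, model, unmix_params or benchmark_unmix_params(model))
    kept = locs[locs["kept"]].reset_index(drop=True)
    truth = scene.truth
    if z_window is not None:
        kept = filter_z_window(kept, z_window)
        truth = filter_z_window(truth, z_window)
    report = match(kept, truth, tol_xy_nm=tol_xy_nm, tol_z_nm=tol_z_nm)
    acc = accuracy_stats(report) if report.n_tp else {}
    return BenchmarkResult(
        metrics=metrics(report), report=report, accuracy=acc,
        scene=scene, locs=locs, z_window=z_window,
    )
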