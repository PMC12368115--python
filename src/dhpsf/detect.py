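"""Candidate finding and 2D Gaussian lobe fitting.

Each DH-PSF lobe is treated as a circularly symmetric 2D Gaussian.
Candidates are local maxima of the Gaussian-smoothed frame above a robust
background threshold (median / 1.4826*MAD); each candidate is then refined
by a least-squares fit of a pixel-integrated Gaussian (flux, centre, width,
offset) on a small window.  Fits that do not converge, drift out of the
window, or land at an implausible width are rejected, and near-duplicate
fits within 1 px of a brighter accepted fit in the same frame are dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.special import erf
from skimage.feature import peak_local_max

from .io import ImageStack, PEAK_COLUMNS

SQRT2 = math.sqrt(2.0)


@dataclass
class DetectionParams:
    """Knobs of the detector.

    ``threshold`` is a multiple of the robust noise standard deviation of
    the smoothed frame; ``sigma_prior_px`` anchors the accepted fitted-width
    interval [0.5, 3] x prior.
    """

    smoothing_sigma_px: float = 1.1
    threshold: float = 4.0
    fit_window_px: int = 9
    max_iterations: int = 100
    min_separation_px: int = 2
    sigma_prior_px: float = 1.1

    def __post_init__(self) -> None:
        if self.fit_window_px < 5 or self.fit_window_px % 2 == 0:
            raise ValueError("fit_window_px must be odd and >= 5")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


def _robust_background(img: np.ndarray):
    bg = float(np.median(img))
    sd = 1.4826 * float(np.median(np.abs(img - bg)))
    return bg, sd


def find_candidates(frame: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Integer (row, col) candidate lobe positions in one frame.

    Local maxima of the smoothed frame exceeding background +
    threshold * sd; maxima closer than ``min_separation_px`` keep only the
    brighter one.  May be empty.
    """
    smoothed = gaussian_filter(np.asarray(frame, dtype=float),
                               params.smoothing_sigma_px)
    bg, sd = _robust_background(smoothed)
    thr = bg + params.threshold * sd + 1e-6 * max(1.0, abs(bg))
    return peak_local_max(
        smoothed,
        min_distance=params.min_separation_px,
        threshold_abs=thr,
        exclude_border=False,
    )


def _integrated_gaussian(coords, flux, x0, y0, sigma, offset):
    xs, ys = coords
    s = abs(sigma) * SQRT2 + 1e-12
    ix = 0.5 * (erf((xs - x0 + 0.5) / s) - erf((xs - x0 - 0.5) / s))
    iy = 0.5 * (erf((ys - y0 + 0.5) / s) - erf((ys - y0 - 0.5) / s))
    return flux * ix * iy + offset


def fit_spot(frame: np.ndarray, candidate, params: DetectionParams):
    """Fit one candidate as a pixel-integrated 2D Gaussian.

    Returns ``(peak_dict, None)`` on success or ``(None, reason)`` on
    rejection.  ``intensity`` is the fitted integrated flux
    (= 2*pi*amplitude*sigma^2 for the equivalent sampled Gaussian).
    """
    row, col = int(candidate[0]), int(candidate[1])
    half = params.fit_window_px // 2
    h, w = frame.shape
    if row - half < 0 or col - half < 0 or row + half >= h or col + half >= w:
        return None, "border"
    window = np.asarray(
        frame[row - half:row + half + 1, col - half:col + half + 1], dtype=float
    )
    if np.ptp(window) < 1e-12:
        return None, "flat"
    ys, xs = np.mgrid[row - half:row + half + 1, col - half:col + half + 1]
    coords = (xs.ravel().astype(float), ys.ravel().astype(float))
    offset0 = float(np.median(window))
    flux0 = max(float(window.sum() - offset0 * window.size),
                float(window.max() - offset0))
    p0 = [flux0, float(col), float(row), params.sigma_prior_px, offset0]
    try:
        with warnings.catch_warnings():
            # a perfect (noiseless) fit has a singular covariance; harmless
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _integrated_gaussian, coords, window.ravel(), p0=p0,
                maxfev=params.max_iterations * 50,
            )
    except RuntimeError:
        return None, "no_convergence"
    flux, x0, y0, sigma, offset = popt
    sigma = abs(sigma)
    if not np.isfinite(flux) or flux <= 1e-6 * np.ptp(window):
        return None, "amplitude"
    if not (0.5 * params.sigma_prior_px <= sigma <= 3.0 * params.sigma_prior_px):
        return None, "sigma"
    if abs(x0 - col) > half or abs(y0 - row) > half:
        return None, "drift"
    return (
        {"x_px": float(x0), "y_px": float(y0), "intensity": float(flux),
         "sigma_px": float(sigma), "background": float(offset)},
        None,
    )


def _subtract_peak(canvas: np.ndarray, peak: dict) -> None:
    """Subtract a fitted Gaussian (without its offset) from a frame, in place."""
    h, w = canvas.shape
    sigma = peak["sigma_px"]
    ext = int(math.ceil(4.0 * sigma + 1.0))
    c = int(round(peak["x_px"]))
    r = int(round(peak["y_px"]))
    c0, c1 = max(c - ext, 0), min(c + ext + 1, w)
    r0, r1 = max(r - ext, 0), min(r + ext + 1, h)
    if c0 >= c1 or r0 >= r1:
        return
    ys, xs = np.mgrid[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] -= _integrated_gaussian(
        (xs.astype(float), ys.astype(float)),
        peak["intensity"], peak["x_px"], peak["y_px"], sigma, 0.0,
    )


def detect_frame(frame: np.ndarray, params: DetectionParams,
                 frame_index: int = 0) -> list[dict]:
    """Detect and fit all lobes in a single frame.

    After a first fitting pass (with duplicate suppression), each spot is
    refitted on the frame with the fitted models of all *other* accepted
    spots subtracted (one deflation pass).  This removes the bias that a
    neighbouring lobe's tail inside the fit window would otherwise imprint
    on the fitted flux and centre.
    """
    fits = []
    for cand in find_candidates(frame, params):
        peak, _reason = fit_spot(frame, cand, params)
        if peak is not None:
            peak["frame"] = int(frame_index)
            peak["candidate"] = (int(cand[0]), int(cand[1]))
            fits.append(peak)
    fits.sort(key=lambda p: -p["intensity"])
    accepted: list[dict] = []
    for peak in fits:
        dup = any(
            (peak["x_px"] - a["x_px"]) ** 2 + (peak["y_px"] - a["y_px"]) ** 2 <= 1.0
            for a in accepted
        )
        if not dup:
            accepted.append(peak)

    if len(accepted) > 1:
        residual = np.asarray(frame, dtype=float).copy()
        for peak in accepted:
            _subtract_peak(residual, peak)
        refined = []
        for peak in accepted:
            # put this spot back onto the deflated frame, refit it alone,
            # then remove it again
            _subtract_peak(residual, {**peak, "intensity": -peak["intensity"]})
            better, _reason = fit_spot(residual, peak["candidate"], params)
            _subtract_peak(residual, peak)
            if better is not None:
                better["frame"] = int(frame_index)
                better["candidate"] = peak["candidate"]
                refined.append(better)
            else:
                refined.append(peak)
        accepted = refined

    for peak in accepted:
        peak.pop("candidate", None)
    accepted.sort(key=lambda p: (p["x_px"], p["y_px"]))
    return accepted


def detect_stack(stack: ImageStack, params: DetectionParams | None = None) -> pd.DataFrame:
    """Detect lobes in every frame of a stack; returns a native peak table."""
    if params is None:
        params = DetectionParams()
    rows: list[dict] = []
    for i in range(stack.n_frames):
        rows.extend(detect_frame(stack.frame(i), params, frame_index=i))
    if not rows:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    df = pd.DataFrame(rows)[PEAK_COLUMNS]
    return df.sort_values("frame", kind="stable").reset_index(drop=True)
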