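"""Calibration of the angle-to-z relation from a single-bead z-stack.

For each usable frame (exactly two fitted lobes) the pair features are
measured: rotation angle theta (folded into [0, 180)), midpoint, interlobe
distance and lobe intensity ratio.  Five polynomial curves are then fitted
against theta — z, midpoint shift dx/dy relative to the first usable frame,
distance and ratio — over the retained angle interval.  The fit uses
numpy's orthogonal-basis least squares with theta rescaled to [-1, 1], so
high degrees (default 15) stay numerically well conditioned.

The calibration series must cover less than 180 degrees of rotation;
non-monotonic angle versus frame (as happens when the series folds past
180 degrees) is rejected with a pointer to ``frame_range`` trimming.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

log = logging.getLogger(__name__)

CURVE_NAMES = ("z", "dx", "dy", "d", "r")


class ThetaRangeError(ValueError):
    """Angle outside the calibrated interval."""


@dataclass
class PairFeatures:
    """Geometric and photometric features of one lobe pair (nm / degrees)."""

    theta_deg: float
    mid_x_nm: float
    mid_y_nm: float
    d_nm: float
    ratio: float
    total_intensity: float


def _value(peak, key):
    try:
        return float(peak[key])
    except (TypeError, IndexError, KeyError):
        return float(getattr(peak, key))


def pair_features(peak_a, peak_b, pixel_size_nm: float) -> PairFeatures:
    """Features of a lobe pair; symmetric under swapping the two peaks.

    theta = atan2(dy, dx) folded into [0, 180); the ratio is the intensity
    of the smaller-x lobe (ties: smaller y) over the other.
    """
    xa, ya, ia = _value(peak_a, "x_px"), _value(peak_a, "y_px"), _value(peak_a, "intensity")
    xb, yb, ib = _value(peak_b, "x_px"), _value(peak_b, "y_px"), _value(peak_b, "intensity")
    dx, dy = xb - xa, yb - ya
    dist_px = math.hypot(dx, dy)
    if dist_px == 0.0:
        raise ValueError("coincident peaks: interlobe distance is zero")
    theta = math.degrees(math.atan2(dy, dx)) % 180.0
    if theta >= 180.0:   # a tiny negative angle can round up to the fold
        theta = 0.0
    if (xa, ya) <= (xb, yb):
        ratio = ia / ib
    else:
        ratio = ib / ia
    return PairFeatures(
        theta_deg=theta,
        mid_x_nm=0.5 * (xa + xb) * pixel_size_nm,
        mid_y_nm=0.5 * (ya + yb) * pixel_size_nm,
        d_nm=dist_px * pixel_size_nm,
        ratio=ratio,
        total_intensity=ia + ib,
    )


@dataclass
class CalibrationModel:
    """Five polynomial curves over a usable angle interval.

    ``curves`` maps each of z (nm), dx/dy (midpoint wobble vs the first
    usable frame, nm), d (interlobe distance, nm) and r (intensity ratio)
    to a :class:`numpy.polynomial.Polynomial` in theta (degrees).
    """

    degree: int
    theta_range: tuple
    pixel_size_nm: float
    z_step_nm: float
    curves: dict
    residual_rms: dict = field(default_factory=dict)
    z0_nm: float = 0.0
    n_frames_used: int = 0

    def in_range(self, theta_deg):
        t = np.asarray(theta_deg, dtype=float)
        lo, hi = self.theta_range
        return (t >= lo) & (t <= hi)

    def evaluate(self, theta_deg, check: bool = True):
        """Evaluate all five curves; raises :class:`ThetaRangeError` when
        ``check`` and any angle is outside ``theta_range``."""
        t = np.asarray(theta_deg, dtype=float)
        if check and not np.all(self.in_range(t)):
            raise ThetaRangeError(
                f"angle outside calibrated range {self.theta_range}"
            )
        return tuple(self.curves[name](t) for name in CURVE_NAMES)

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "theta_range": list(self.theta_range),
            "pixel_size_nm": self.pixel_size_nm,
            "z_step_nm": self.z_step_nm,
            "z0_nm": self.z0_nm,
            "n_frames_used": self.n_frames_used,
            "residual_rms": dict(self.residual_rms),
            "curves": {
                name: {
                    "coef": list(map(float, p.coef)),
                    "domain": list(map(float, p.domain)),
                }
                for name, p in self.curves.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CalibrationModel":
        curves = {
            name: Polynomial(spec["coef"], domain=spec["domain"], window=[-1, 1])
            for name, spec in payload["curves"].items()
        }
        return cls(
            degree=int(payload["degree"]),
            theta_range=tuple(payload["theta_range"]),
            pixel_size_nm=float(payload["pixel_size_nm"]),
            z_step_nm=float(payload["z_step_nm"]),
            curves=curves,
            residual_rms=dict(payload.get("residual_rms", {})),
            z0_nm=float(payload.get("z0_nm", 0.0)),
            n_frames_used=int(payload.get("n_frames_used", 0)),
        )


def extract_pair_features(peaks: pd.DataFrame, z_step_nm: float,
                          pixel_size_nm: float, frame_range: tuple | None = None,
                          z0_nm: float = 0.0) -> pd.DataFrame:
    """Per-frame pair features of a single-bead calibration peak table.

    Frames contributing a number of peaks other than two are skipped with a
    warning.  The known z of frame i is ``z0_nm + i * z_step_nm``.
    """
    df = peaks
    if frame_range is not None:
        lo, hi = frame_range
        df = df[(df["frame"] >= lo) & (df["frame"] <= hi)]
    rows = []
    n_skipped = 0
    for frame, grp in df.groupby("frame", sort=True):
        if len(grp) != 2:
            n_skipped += 1
            continue
        feats = pair_features(grp.iloc[0], grp.iloc[1], pixel_size_nm)
        rows.append({
            "frame": int(frame),
            "z_nm": z0_nm + int(frame) * z_step_nm,
            "theta_deg": feats.theta_deg,
            "mid_x_nm": feats.mid_x_nm,
            "mid_y_nm": feats.mid_y_nm,
            "d_nm": feats.d_nm,
            "ratio": feats.ratio,
            "total_intensity": feats.total_intensity,
        })
    if n_skipped:
        log.warning("calibration: skipped %d frames without exactly 2 peaks", n_skipped)
    return pd.DataFrame(rows)


def build_calibration(peaks: pd.DataFrame, z_step_nm: float,
                      pixel_size_nm: float, degree: int = 15,
                      frame_range: tuple | None = None,
                      z0_nm: float = 0.0) -> CalibrationModel:
    """Fit the five calibration curves from a single-bead peak table."""
    feats = extract_pair_features(peaks, z_step_nm, pixel_size_nm,
                                  frame_range=frame_range, z0_nm=z0_nm)
    if len(feats) < degree + 2:
        raise ValueError(
            f"only {len(feats)} usable frames; need at least degree+2 = {degree + 2}"
        )
    theta = feats["theta_deg"].to_numpy()
    diffs = np.diff(theta)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError(
            "rotation angle is not monotonic across calibration frames "
            "(the series may fold past 180 degrees); restrict frame_range "
            "to a monotonic sub-interval"
        )
    span = float(theta.max() - theta.min())
    if span > 180.0:
        raise ValueError("calibration series covers more than 180 degrees")

    targets = {
        "z": feats["z_nm"].to_numpy(),
        "dx": feats["mid_x_nm"].to_numpy() - feats["mid_x_nm"].iloc[0],
        "dy": feats["mid_y_nm"].to_numpy() - feats["mid_y_nm"].iloc[0],
        "d": feats["d_nm"].to_numpy(),
        "r": feats["ratio"].to_numpy(),
    }
    curves = {}
    residual_rms = {}
    for name, y in targets.items():
        # Polynomial.fit maps theta onto the [-1, 1] window internally,
        # keeping degree-15 fits well conditioned.
        curves[name] = Polynomial.fit(theta, y, degree)
        resid = y - curves[name](theta)
        residual_rms[name] = float(np.sqrt(np.mean(resid ** 2)))
    return CalibrationModel(
        degree=degree,
        theta_range=(float(theta.min()), float(theta.max())),
        pixel_size_nm=pixel_size_nm,
        z_step_nm=z_step_nm,
        curves=curves,
        residual_rms=residual_rms,
        z0_nm=z0_nm,
        n_frames_used=len(feats),
    )


def evaluate_model(model: CalibrationModel, theta_deg):
    """``(z, dx, dy, d, ratio)`` at the given angle(s); raises
    :class:`ThetaRangeError` outside the calibrated interval."""
    return model.evaluate(theta_deg, check=True)


def calibration_diagnostics(model: CalibrationModel, features: pd.DataFrame,
                            out_dir=None) -> dict:
    """Residual summary, monotonicity flags and suggested angle trimming.

    ``features`` is the table from :func:`extract_pair_features`.  When
    ``out_dir`` is given, a five-panel plot of the measured features and
    fitted curves is written there as ``calibration_diagnostics.png``.
    """
    theta = features["theta_deg"].to_numpy()
    diffs = np.diff(theta)
    theta_monotonic = bool(np.all(diffs > 0) or np.all(diffs < 0))

    lo, hi = model.theta_range
    dense = np.linspace(lo, hi, 1000)
    z_dense = model.curves["z"](dense)
    dz = np.diff(z_dense)
    z_monotonic = bool(np.all(dz > 0) or np.all(dz < 0))

    targets = {
        "z": features["z_nm"].to_numpy(),
        "dx": features["mid_x_nm"].to_numpy() - features["mid_x_nm"].iloc[0],
        "dy": features["mid_y_nm"].to_numpy() - features["mid_y_nm"].iloc[0],
        "d": features["d_nm"].to_numpy(),
        "r": features["ratio"].to_numpy(),
    }
    residual_rms = {}
    per_point = {}
    for name, y in targets.items():
        resid = y - model.curves[name](theta)
        residual_rms[name] = float(np.sqrt(np.mean(resid ** 2)))
        per_point[name] = resid

    # suggest trimming where the z residual exceeds 3x the median |residual|
    zres = np.abs(per_point["z"])
    scale = max(float(np.median(zres)), 1e-12)
    ok = zres <= 3.0 * scale
    i0, i1 = 0, len(theta) - 1
    while i0 < i1 and not ok[i0]:
        i0 += 1
    while i1 > i0 and not ok[i1]:
        i1 -= 1
    suggested = (float(min(theta[i0], theta[i1])), float(max(theta[i0], theta[i1])))

    report = {
        "residual_rms": residual_rms,
        "theta_monotonic": theta_monotonic,
        "z_monotonic": z_monotonic,
        "theta_range": tuple(model.theta_range),
        "suggested_theta_range": suggested,
        "n_frames_used": int(len(features)),
    }
    if out_dir is not None:
        _plot_diagnostics(model, features, targets, report, out_dir)
    return report


def _plot_diagnostics(model, features, targets, report, out_dir):
    from pathlib import Path

    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    theta = features["theta_deg"].to_numpy()
    lo, hi = model.theta_range
    dense = np.linspace(lo, hi, 500)
    labels = {"z": "z (nm)", "dx": "midpoint shift x (nm)",
              "dy": "midpoint shift y (nm)", "d": "interlobe distance (nm)",
              "r": "intensity ratio"}
    fig = Figure(figsize=(12, 7))
    FigureCanvasAgg(fig)
    for k, name in enumerate(CURVE_NAMES):
        ax = fig.add_subplot(2, 3, k + 1)
        ax.plot(theta, targets[name], "k+", ms=4, label="measured")
        ax.plot(dense, model.curves[name](dense), "-", color="tab:orange",
                label=f"degree-{model.degree} fit")
        ax.set_xlabel("rotation angle (deg)")
        ax.set_ylabel(labels[name])
        ax.legend(fontsize=7)
    ax = fig.add_subplot(2, 3, 6)
    ax.axis("off")
    lines = [f"{k}: rms={v:.3g}" for k, v in report["residual_rms"].items()]
    lines.append(f"theta monotonic: {report['theta_monotonic']}")
    lines.append(f"z(theta) monotonic: {report['z_monotonic']}")
    lines.append("suggested range: "
                 f"[{report['suggested_theta_range'][0]:.1f}, "
                 f"{report['suggested_theta_range'][1]:.1f}] deg")
    ax.text(0.0, 0.9, "\n".join(lines), va="top", fontsize=9, family="monospace")
    fig.tight_layout()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fig.savefig(out / "calibration_diagnostics.png", dpi=120)
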