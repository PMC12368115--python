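"""Lobe pairing and 3D localisation.

Per frame, the pairwise Euclidean distance matrix of the fitted lobes is
computed and peaks whose separation falls inside the expected interlobe
range become candidate pairs.  Conflicts are resolved greedily: candidates
sorted by the absolute deviation of their separation from the centre of the
allowed range, accepted only when neither peak is already used (index
tie-break, fully deterministic).  Each accepted pair is localised — z from
the rotation angle via the calibration, xy from the wobble-corrected
midpoint — and then filtered against the calibration-expected interlobe
distance (fractional tolerance) and intensity ratio (symmetric log-scale
tolerance), so a ratio r and its inverse deviate equally.

Pairs whose angle falls outside the calibrated interval cannot be assigned
a z and are marked rejected (``angle_range``); unpaired peaks are treated
as noise and produce no localisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .calibrate import CalibrationModel, pair_features
from .io import LOC_COLUMNS

log = logging.getLogger(__name__)

REJECT_NONE = "none"
REJECT_ANGLE = "angle_range"
REJECT_DISTANCE = "distance"
REJECT_RATIO = "ratio"


@dataclass
class UnmixParams:
    """Pairing range and calibration-relative filter tolerances."""

    d_min_nm: float
    d_max_nm: float
    pixel_size_nm: float
    tol_d: float = 0.25
    tol_r: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.d_min_nm < self.d_max_nm:
            raise ValueError("require 0 < d_min_nm < d_max_nm")
        if self.tol_d <= 0 or self.tol_r <= 0:
            raise ValueError("tolerances must be positive")

    @classmethod
    def from_model(cls, model: CalibrationModel, low: float = 0.8,
                   high: float = 1.2, **kwargs) -> "UnmixParams":
        """Anchor the pairing range to the calibration's distance curve:
        [low * min d(theta), high * max d(theta)]."""
        lo, hi = model.theta_range
        d = model.curves["d"](np.linspace(lo, hi, 500))
        return cls(
            d_min_nm=low * float(d.min()),
            d_max_nm=high * float(d.max()),
            pixel_size_nm=model.pixel_size_nm,
            **kwargs,
        )


def pair_peaks(frame_peaks: pd.DataFrame, params: UnmixParams):
    """Greedy minimal-deviation pairing of the peaks of one frame.

    Returns ``(pairs, unpaired)`` where ``pairs`` is a list of positional
    index tuples (i, j), i < j, into ``frame_peaks``, and ``unpaired`` the
    remaining positional indices.  Deterministic; each peak appears in at
    most one pair.
    """
    n = len(frame_peaks)
    if n < 2:
        return [], list(range(n))
    xy = frame_peaks[["x_px", "y_px"]].to_numpy(dtype=float) * params.pixel_size_nm
    dist = squareform(pdist(xy))
    centre = 0.5 * (params.d_min_nm + params.d_max_nm)
    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if params.d_min_nm <= d <= params.d_max_nm:
                candidates.append((abs(d - centre), i, j))
    candidates.sort()
    used = np.zeros(n, dtype=bool)
    pairs = []
    for _dev, i, j in candidates:
        if not used[i] and not used[j]:
            used[i] = used[j] = True
            pairs.append((i, j))
    unpaired = [k for k in range(n) if not used[k]]
    return pairs, unpaired


def localise(peak_a, peak_b, model: CalibrationModel, params: UnmixParams) -> dict:
    """One pair -> one localisation row (pre-filter).

    z is read off the calibration's z(theta) curve; xy is the midpoint minus
    the calibration wobble at that angle.  Angles outside the calibrated
    interval yield ``kept=False`` with reason ``angle_range`` and undefined z.
    """
    feats = pair_features(peak_a, peak_b, params.pixel_size_nm)
    row = {
        "frame": int(_get(peak_a, "frame")),
        "intensity": feats.total_intensity,
        "angle_deg": feats.theta_deg,
        "interlobe_nm": feats.d_nm,
        "ratio": feats.ratio,
    }
    if not model.in_range(feats.theta_deg):
        row.update(x_nm=feats.mid_x_nm, y_nm=feats.mid_y_nm, z_nm=np.nan,
                   kept=False, reject_reason=REJECT_ANGLE)
        return row
    z, dx, dy, _d, _r = model.evaluate(feats.theta_deg, check=False)
    row.update(
        x_nm=feats.mid_x_nm - float(dx),
        y_nm=feats.mid_y_nm - float(dy),
        z_nm=float(z),
        kept=True,
        reject_reason=REJECT_NONE,
    )
    return row


def _get(peak, key):
    try:
        return peak[key]
    except (TypeError, IndexError, KeyError):
        return getattr(peak, key)


def apply_filters(loc: dict, model: CalibrationModel, params: UnmixParams) -> dict:
    """Calibration-relative distance and ratio filters (in place and returned)."""
    if loc.get("reject_reason") != REJECT_NONE:
        return loc
    _z, _dx, _dy, d_exp, r_exp = model.evaluate(loc["angle_deg"], check=False)
    d_exp, r_exp = float(d_exp), float(r_exp)
    if abs(loc["interlobe_nm"] - d_exp) > params.tol_d * d_exp:
        loc["kept"] = False
        loc["reject_reason"] = REJECT_DISTANCE
    elif abs(math.log(loc["ratio"]) - math.log(r_exp)) > math.log1p(params.tol_r):
        loc["kept"] = False
        loc["reject_reason"] = REJECT_RATIO
    return loc


def unmix_stack(peaks: pd.DataFrame, model: CalibrationModel,
                params: UnmixParams | None = None) -> pd.DataFrame:
    """Pair, localise and filter a whole peak table, frame by frame."""
    if params is None:
        params = UnmixParams.from_model(model)
    rows: list[dict] = []
    for _frame, grp in peaks.groupby("frame", sort=True):
        grp = grp.reset_index(drop=True)
        pairs, _unpaired = pair_peaks(grp, params)
        for i, j in pairs:
            loc = localise(grp.iloc[i], grp.iloc[j], model, params)
            loc = apply_filters(loc, model, params)
            rows.append(loc)
    if not rows:
        return pd.DataFrame(columns=LOC_COLUMNS)
    locs = pd.DataFrame(rows)[LOC_COLUMNS]
    counts = locs["reject_reason"].value_counts().to_dict()
    log.info("unmix: %d localisations, rejects by reason: %s",
             int(locs["kept"].sum()), {k: v for k, v in counts.items() if k != REJECT_NONE})
    return locs.reset_index(drop=True)
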