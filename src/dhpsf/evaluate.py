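"""Benchmarking localisation tables against ground truth.

Detected and true localisations are matched one-to-one, per frame, by a
greedy ascending-3D-distance rule among candidates within lateral and axial
tolerance.  From the resulting TP/FP/FN assignment the standard detection
metrics follow: precision = TP/(TP+FP), sensitivity = TP/(TP+FN) and the
Jaccard index TP/(TP+FP+FN), plus localisation-accuracy distributions
(distances between matched detected and true positions), sensitivity as a
function of z, a global-translation correction, and the eligibility filters
used when benchmarking against reference datasets (border exclusion and
removal of the dimmest fraction of truths).

The matching tolerances default to 250 nm laterally and 500 nm axially and
are always recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

COORDS = ["x_nm", "y_nm", "z_nm"]


@dataclass
class MatchReport:
    """One-to-one TP assignment plus FP/FN bookkeeping.

    ``pairs`` has one row per true positive: positional ids into the
    detected and truth tables, the xy / z / 3D distances, and the signed
    (detected - truth) offsets used by the translation correction.
    """

    pairs: pd.DataFrame
    n_tp: int
    n_fp: int
    n_fn: int
    tol_xy_nm: float
    tol_z_nm: float
    unmatched_detected: list = field(default_factory=list)
    unmatched_truth: list = field(default_factory=list)


class Metrics(NamedTuple):
    precision: float
    sensitivity: float
    jaccard: float


def match(detected: pd.DataFrame, truth: pd.DataFrame,
          tol_xy_nm: float = 250.0, tol_z_nm: float = 500.0,
          same_frame: bool = True) -> MatchReport:
    """Greedy one-to-one matching by ascending 3D distance.

    Candidates satisfy d_xy <= tol_xy and |d_z| <= tol_z (and share a frame
    when ``same_frame``).  Unmatched detections are false positives,
    unmatched truths false negatives.
    """
    det = detected.reset_index(drop=True)
    tru = truth.reset_index(drop=True)
    pair_rows = []
    used_det = np.zeros(len(det), dtype=bool)
    used_tru = np.zeros(len(tru), dtype=bool)

    if same_frame:
        det_groups = {f: g for f, g in det.groupby("frame")}
        tru_groups = {f: g for f, g in tru.groupby("frame")}
        frames = sorted(set(det_groups) | set(tru_groups))
        blocks = [(det_groups.get(f), tru_groups.get(f)) for f in frames]
    else:
        blocks = [(det, tru)]

    for dblk, tblk in blocks:
        if dblk is None or tblk is None or len(dblk) == 0 or len(tblk) == 0:
            continue
        d_xyz = dblk[COORDS].to_numpy(dtype=float)
        t_xyz = tblk[COORDS].to_numpy(dtype=float)
        dxy = np.hypot(d_xyz[:, None, 0] - t_xyz[None, :, 0],
                       d_xyz[:, None, 1] - t_xyz[None, :, 1])
        dz = d_xyz[:, None, 2] - t_xyz[None, :, 2]
        ok = (dxy <= tol_xy_nm) & (np.abs(dz) <= tol_z_nm)
        if not ok.any():
            continue
        d3 = np.sqrt(dxy ** 2 + dz ** 2)
        di, ti = np.nonzero(ok)
        order = np.lexsort((ti, di, d3[di, ti]))
        for k in order:
            i, j = di[k], ti[k]
            gi, gj = dblk.index[i], tblk.index[j]
            if used_det[gi] or used_tru[gj]:
                continue
            used_det[gi] = used_tru[gj] = True
            pair_rows.append({
                "detected_id": int(gi), "truth_id": int(gj),
                "d_xy_nm": float(dxy[i, j]), "d_z_nm": float(abs(dz[i, j])),
                "d_3d_nm": float(d3[i, j]),
                "dx_nm": float(d_xyz[i, 0] - t_xyz[j, 0]),
                "dy_nm": float(d_xyz[i, 1] - t_xyz[j, 1]),
                "dz_nm": float(dz[i, j]),
            })

    pairs = pd.DataFrame(
        pair_rows,
        columns=["detected_id", "truth_id", "d_xy_nm", "d_z_nm", "d_3d_nm",
                 "dx_nm", "dy_nm", "dz_nm"],
    )
    n_tp = len(pairs)
    return MatchReport(
        pairs=pairs,
        n_tp=n_tp,
        n_fp=len(det) - n_tp,
        n_fn=len(tru) - n_tp,
        tol_xy_nm=tol_xy_nm,
        tol_z_nm=tol_z_nm,
        unmatched_detected=list(np.nonzero(~used_det)[0]),
        unmatched_truth=list(np.nonzero(~used_tru)[0]),
    )


def metrics(report: MatchReport) -> Metrics:
    """Precision, sensitivity and Jaccard; NaN flags a zero denominator."""
    tp, fp, fn = report.n_tp, report.n_fp, report.n_fn
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    sensitivity = tp / (tp + fn) if tp + fn > 0 else float("nan")
    jaccard = tp / (tp + fp + fn) if tp + fp + fn > 0 else float("nan")
    return Metrics(precision, sensitivity, jaccard)


def accuracy_stats(report: MatchReport) -> dict:
    """Median localisation-accuracy distances plus the full distributions."""
    if report.n_tp < 1:
        raise ValueError("accuracy_stats requires at least one true positive")
    p = report.pairs
    return {
        "median_d_xy_nm": float(p["d_xy_nm"].median()),
        "median_d_z_nm": float(p["d_z_nm"].median()),
        "median_d_3d_nm": float(p["d_3d_nm"].median()),
        "d_xy_nm": p["d_xy_nm"].to_numpy(),
        "d_z_nm": p["d_z_nm"].to_numpy(),
        "d_3d_nm": p["d_3d_nm"].to_numpy(),
    }


def sensitivity_vs_z(report: MatchReport, truth: pd.DataFrame,
                     bin_nm: float = 250.0) -> pd.DataFrame:
    """Per-z-bin sensitivity with bin-wise FN accounting.

    Bins without truths are omitted.  Returns columns
    ``z_center_nm, n_truth, n_tp, sensitivity``.
    """
    tru = truth.reset_index(drop=True)
    z = tru["z_nm"].to_numpy(dtype=float)
    lo, hi = z.min(), z.max()
    n_bins = max(int(np.ceil((hi - lo) / bin_nm)), 1)
    edges = lo + bin_nm * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    matched = np.zeros(len(tru), dtype=bool)
    matched[report.pairs["truth_id"].to_numpy(dtype=int)] = True
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n_truth = int(mask.sum())
        if n_truth == 0:
            continue
        n_tp = int(matched[mask].sum())
        rows.append({
            "z_center_nm": float(edges[b] + 0.5 * bin_nm),
            "n_truth": n_truth, "n_tp": n_tp,
            "sensitivity": n_tp / n_truth,
        })
    return pd.DataFrame(rows)


def translation_correct(detected: pd.DataFrame, report: MatchReport) -> pd.DataFrame:
    """Remove a global translation: subtract the mean (detected - truth)
    offset over true positives from every detected coordinate."""
    if report.n_tp < 1:
        raise ValueError("translation_correct requires at least one true positive")
    out = detected.reset_index(drop=True).copy()
    out["x_nm"] = out["x_nm"] - float(report.pairs["dx_nm"].mean())
    out["y_nm"] = out["y_nm"] - float(report.pairs["dy_nm"].mean())
    out["z_nm"] = out["z_nm"] - float(report.pairs["dz_nm"].mean())
    return out


def eligibility_filters(truth: pd.DataFrame, border_nm: float = 0.0,
                        dimmest_fraction: float = 0.25,
                        extent_nm: tuple | None = None,
                        intensity_column: str = "intensity_factor") -> pd.DataFrame:
    """Benchmark eligibility: drop truths near the canvas border and the
    dimmest fraction by intensity.

    ``extent_nm`` is the (width, height) of the field in nm; when omitted
    the bounding box of the truths is used.  Both predicates are evaluated
    on the input table (the dimmest-fraction threshold is a rank cut of the
    input intensities), so the filters commute.
    """
    if not 0.0 <= dimmest_fraction < 1.0:
        raise ValueError("dimmest_fraction must lie in [0, 1)")
    out = truth.reset_index(drop=True)
    keep = np.ones(len(out), dtype=bool)
    if border_nm > 0:
        if extent_nm is None:
            x0, x1 = out["x_nm"].min(), out["x_nm"].max()
            y0, y1 = out["y_nm"].min(), out["y_nm"].max()
        else:
            x0, y0 = 0.0, 0.0
            x1, y1 = extent_nm
        keep &= (
            (out["x_nm"] >= x0 + border_nm) & (out["x_nm"] <= x1 - border_nm)
            & (out["y_nm"] >= y0 + border_nm) & (out["y_nm"] <= y1 - border_nm)
        ).to_numpy()
    if dimmest_fraction > 0 and len(out) > 0:
        n_drop = int(np.floor(dimmest_fraction * len(out)))
        if n_drop > 0:
            order = out[intensity_column].to_numpy().argsort(kind="stable")
            dim = np.zeros(len(out), dtype=bool)
            dim[order[:n_drop]] = True
            keep &= ~dim
    return out[keep].reset_index(drop=True)


def filter_z_window(table: pd.DataFrame, z_window: tuple) -> pd.DataFrame:
    """Rows whose z lies inside [z_lo, z_hi] (restricted-range evaluation)."""
    lo, hi = z_window
    return table[(table["z_nm"] >= lo) & (table["z_nm"] <= hi)].reset_index(drop=True)
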