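"""Post-processing of 3D localisation tables.

Three tools commonly applied after localisation:

* lateral drift correction, either by cross-correlating 2D histogram
  renderings of temporal blocks (with parabolic sub-pixel peak refinement
  and per-frame linear interpolation) or by subtracting a fiducial track;
* blinking correction: transitive grouping of localisations that recur in
  nearby positions within a frame gap, each connected component collapsing
  to one molecule with mean coordinates and summed intensity;
* Fourier shell correlation (FSC): the localisations are randomly split in
  half, each half voxelised and Gaussian-blurred, and the correlation of
  the two 3D Fourier transforms is computed per spherical frequency shell;
  the resolution is read at the first descent through the 1/7 threshold.
  A block-wise variant maps resolution across 1 um blocks of a large
  volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import fftfreq, fftn, next_fast_len
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# drift correction
# --------------------------------------------------------------------------

@dataclass
class DriftTrace:
    """Per-block lateral shifts relative to a reference block."""

    blocks: pd.DataFrame    # frame_start, frame_end, shift_x_nm, shift_y_nm
    reference_block: int = 0

    def per_frame(self, frames: np.ndarray) -> np.ndarray:
        """Linearly interpolated (shift_x, shift_y) for each frame."""
        centers = 0.5 * (self.blocks["frame_start"] + self.blocks["frame_end"])
        fx = np.interp(frames, centers, self.blocks["shift_x_nm"])
        fy = np.interp(frames, centers, self.blocks["shift_y_nm"])
        return np.column_stack([fx, fy])


def _xcorr_shift(ref: np.ndarray, img: np.ndarray) -> tuple[float, float]:
    """Shift (dy, dx) in bins such that img ~= ref translated by that shift."""
    f = np.fft.rfft2(ref) * np.conj(np.fft.rfft2(img))
    corr = np.fft.irfft2(f, s=ref.shape)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shift = []
    for axis, p in enumerate(peak):
        n = corr.shape[axis]
        # parabolic refinement through the wrapped neighbours
        idx = [(p - 1) % n, p, (p + 1) % n]
        sel = [slice(None)] * corr.ndim
        vals = []
        for i in idx:
            sel[axis] = i
            other = peak[1 - axis]
            vals.append(corr[tuple(i if a == axis else other for a in range(2))])
        y0, y1, y2 = vals
        denom = y0 - 2 * y1 + y2
        frac = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-30 else 0.0
        s = p + frac
        if s > n / 2:
            s -= n
        shift.append(-s)
    return shift[0], shift[1]   # (dy, dx)


def estimate_drift_xcorr(locs: pd.DataFrame, block_frames: int,
                         bin_nm: float = 50.0) -> DriftTrace:
    """Estimate lateral drift by cross-correlating block-wise 2D histograms.

    Frames are tiled into blocks of ``block_frames``; each block is rendered
    as a 2D histogram with ``bin_nm`` bins and cross-correlated against the
    first block.  Empty blocks inherit the previous block's shift with a
    warning.
    """
    f0, f1 = int(locs["frame"].min()), int(locs["frame"].max())
    edges = list(range(f0, f1 + 1, block_frames))
    x = locs["x_nm"].to_numpy(dtype=float)
    y = locs["y_nm"].to_numpy(dtype=float)
    frames = locs["frame"].to_numpy()
    x_edges = np.arange(x.min() - bin_nm, x.max() + 2 * bin_nm, bin_nm)
    y_edges = np.arange(y.min() - bin_nm, y.max() + 2 * bin_nm, bin_nm)

    hists, ranges = [], []
    for start in edges:
        end = min(start + block_frames - 1, f1)
        mask = (frames >= start) & (frames <= end)
        hist, _, _ = np.histogram2d(y[mask], x[mask], bins=[y_edges, x_edges])
        hists.append(hist)
        ranges.append((start, end))
    if sum(h.sum() > 0 for h in hists) < 1:
        raise ValueError("no localisations in any block")

    ref_idx = next(i for i, h in enumerate(hists) if h.sum() > 0)
    ref = hists[ref_idx]
    rows = []
    prev = (0.0, 0.0)
    for k, (hist, (start, end)) in enumerate(zip(hists, ranges)):
        if k == ref_idx:
            sx = sy = 0.0
        elif hist.sum() == 0:
            log.warning("drift: block %d (frames %d-%d) empty; carrying "
                        "previous shift", k, start, end)
            sx, sy = prev
        else:
            dy, dx = _xcorr_shift(ref, hist)
            sx, sy = dx * bin_nm, dy * bin_nm
        prev = (sx, sy)
        rows.append({"frame_start": start, "frame_end": end,
                     "shift_x_nm": sx, "shift_y_nm": sy})
    return DriftTrace(blocks=pd.DataFrame(rows), reference_block=ref_idx)


def apply_drift(locs: pd.DataFrame, trace: DriftTrace,
                subtract: bool = True) -> pd.DataFrame:
    """Subtract (or re-add, ``subtract=False``) the interpolated drift."""
    out = locs.reset_index(drop=True).copy()
    shifts = trace.per_frame(out["frame"].to_numpy(dtype=float))
    sign = -1.0 if subtract else 1.0
    out["x_nm"] = out["x_nm"] + sign * shifts[:, 0]
    out["y_nm"] = out["y_nm"] + sign * shifts[:, 1]
    return out


def fiducial_drift(locs: pd.DataFrame, fiducial_track: pd.DataFrame) -> pd.DataFrame:
    """Subtract a fiducial bead's (mean-centred) track from each localisation.

    ``fiducial_track`` has columns ``frame, x_nm, y_nm``; gaps in the track
    are linearly interpolated (and logged).
    """
    track = fiducial_track.sort_values("frame").reset_index(drop=True)
    tf = track["frame"].to_numpy(dtype=float)
    lf = locs["frame"].to_numpy(dtype=float)
    if lf.min() > tf.max() or lf.max() < tf.min():
        raise ValueError("fiducial track does not overlap the data frames")
    missing = set(np.unique(lf).astype(int)) - set(tf.astype(int))
    if missing:
        log.info("fiducial_drift: interpolating %d frames absent from the track",
                 len(missing))
    mx, my = track["x_nm"].mean(), track["y_nm"].mean()
    sx = np.interp(lf, tf, track["x_nm"].to_numpy(dtype=float)) - mx
    sy = np.interp(lf, tf, track["y_nm"].to_numpy(dtype=float)) - my
    out = locs.reset_index(drop=True).copy()
    out["x_nm"] = out["x_nm"] - sx
    out["y_nm"] = out["y_nm"] - sy
    return out


# --------------------------------------------------------------------------
# blinking correction
# --------------------------------------------------------------------------

class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def group_blinking(locs: pd.DataFrame, dxy_max_nm: float = 150.0,
                   dz_max_nm: float | None = None,
                   max_gap_frames: int = 50) -> pd.DataFrame:
    """Merge repeated appearances of blinking molecules.

    Two localisations are linked when their lateral distance is below
    ``dxy_max_nm`` (and |dz| below ``dz_max_nm`` if given) and their frame
    difference is at most ``max_gap_frames``; linking is transitive, so each
    connected component collapses to one row with unweighted mean
    coordinates, summed intensity, the first frame, and a ``multiplicity``
    count.
    """
    df = locs.reset_index(drop=True)
    n = len(df)
    if n == 0:
        out = df.copy()
        out["multiplicity"] = pd.Series(dtype=int)
        return out
    frames = df["frame"].to_numpy(dtype=int)
    xy = df[["x_nm", "y_nm"]].to_numpy(dtype=float)
    z = df["z_nm"].to_numpy(dtype=float) if "z_nm" in df.columns else None

    dsu = _DisjointSet(n)
    order = np.argsort(frames, kind="stable")
    unique_frames = np.unique(frames)
    by_frame = {f: np.nonzero(frames == f)[0] for f in unique_frames}
    trees = {f: cKDTree(xy[idx]) for f, idx in by_frame.items()}
    for fi, f in enumerate(unique_frames):
        for g in unique_frames[fi:]:
            if g - f > max_gap_frames:
                break
            pairs = trees[f].query_ball_tree(trees[g], r=dxy_max_nm)
            ia, ib = by_frame[f], by_frame[g]
            for a_local, neigh in enumerate(pairs):
                a = ia[a_local]
                for b_local in neigh:
                    b = ib[b_local]
                    if b == a:
                        continue
                    d = np.hypot(*(xy[a] - xy[b]))
                    if d >= dxy_max_nm:
                        continue
                    if dz_max_nm is not None and z is not None \
                            and abs(z[a] - z[b]) >= dz_max_nm:
                        continue
                    dsu.union(a, b)

    roots = np.array([dsu.find(i) for i in range(n)])
    rows = []
    for root in np.unique(roots[order], ):
        members = np.nonzero(roots == root)[0]
        sub = df.iloc[members]
        row = {
            "frame": int(sub["frame"].min()),
            "x_nm": float(sub["x_nm"].mean()),
            "y_nm": float(sub["y_nm"].mean()),
            "intensity": float(sub["intensity"].sum()) if "intensity" in sub else np.nan,
            "multiplicity": int(len(sub)),
        }
        if z is not None:
            row["z_nm"] = float(sub["z_nm"].mean())
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("frame", kind="stable").reset_index(drop=True)
    out["kept"] = True
    return out


# --------------------------------------------------------------------------
# Fourier shell correlation
# --------------------------------------------------------------------------

@dataclass
class FscResult:
    """FSC curve and the threshold-crossing resolution."""

    frequencies_per_nm: np.ndarray
    correlation: np.ndarray
    resolution_nm: float
    threshold: float
    n_half1: int = 0
    n_half2: int = 0


def _voxelise(xyz: np.ndarray, origin: np.ndarray, side: int,
              voxel_nm: float) -> np.ndarray:
    idx = np.floor((xyz - origin) / voxel_nm).astype(int)
    idx = np.clip(idx, 0, side - 1)
    vol = np.zeros((side, side, side), dtype=float)
    np.add.at(vol, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    return vol


def fsc_curve(vol1: np.ndarray, vol2: np.ndarray, voxel_nm: float):
    """Shell-wise correlation of two equally shaped cubic volumes."""
    if vol1.shape != vol2.shape:
        raise ValueError("volumes must share a shape")
    n = vol1.shape[0]
    f1 = fftn(vol1)
    f2 = fftn(vol2)
    freq = fftfreq(n, d=voxel_nm)
    fx, fy, fz = np.meshgrid(freq, freq, freq, indexing="ij")
    radius = np.sqrt(fx ** 2 + fy ** 2 + fz ** 2)
    df = 1.0 / (n * voxel_nm)
    shell = np.rint(radius / df).astype(int)
    n_shells = n // 2 + 1
    mask = shell < n_shells
    s = shell[mask]
    num = np.bincount(s, weights=(f1 * np.conj(f2)).real[mask], minlength=n_shells)
    d1 = np.bincount(s, weights=(np.abs(f1) ** 2)[mask], minlength=n_shells)
    d2 = np.bincount(s, weights=(np.abs(f2) ** 2)[mask], minlength=n_shells)
    denom = np.sqrt(d1 * d2)
    fsc = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    freqs = df * np.arange(n_shells)
    return freqs, fsc


def _resolution_from_curve(freqs: np.ndarray, fsc: np.ndarray,
                           threshold: float, voxel_nm: float) -> float:
    below = np.nonzero(fsc[1:] < threshold)[0]
    if len(below) == 0:
        return 2.0 * voxel_nm     # never drops: resolution at Nyquist
    k = below[0] + 1
    f_lo, f_hi = freqs[k - 1], freqs[k]
    c_lo, c_hi = fsc[k - 1], fsc[k]
    if c_lo == c_hi:
        f_cross = f_hi
    else:
        f_cross = f_lo + (c_lo - threshold) * (f_hi - f_lo) / (c_lo - c_hi)
    return 1.0 / f_cross


def fsc_resolution(locs: pd.DataFrame, voxel_nm: float = 5.0,
                   blur_sigma_vox: tuple = (3.0, 3.0, 5.0),
                   threshold: float = 1.0 / 7.0, seed: int = 0,
                   split: bool = True, max_side: int = 512) -> FscResult:
    """FSC resolution of a localisation table.

    The data are randomly half-split (seeded), voxelised into cubes of
    ``voxel_nm`` voxels, blurred with a 3D Gaussian of ``blur_sigma_vox``
    (sigma, in voxels, per axis), and correlated shell by shell; the
    resolution is 1/frequency at the first descent through ``threshold``.
    ``split=False`` correlates the full set with itself (a self-test: the
    curve is identically 1).
    """
    if len(locs) < 2:
        raise ValueError("FSC requires at least 2 localisations")
    xyz = locs[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    origin = xyz.min(axis=0)
    extent = xyz.max(axis=0) - origin
    side = int(np.ceil(extent.max() / voxel_nm)) + 1
    side = next_fast_len(max(side, 8))
    if side > max_side:
        raise ValueError(
            f"volume of {side}^3 voxels exceeds max_side={max_side}; "
            "increase voxel_nm or crop the data"
        )
    rng = np.random.default_rng(seed)
    if split:
        half = rng.random(len(xyz)) < 0.5
        set1, set2 = xyz[half], xyz[~half]
        if len(set1) == 0 or len(set2) == 0:
            raise ValueError("random split produced an empty half")
    else:
        set1 = set2 = xyz
    vol1 = gaussian_filter(_voxelise(set1, origin, side, voxel_nm), blur_sigma_vox)
    vol2 = gaussian_filter(_voxelise(set2, origin, side, voxel_nm), blur_sigma_vox)
    freqs, fsc = fsc_curve(vol1, vol2, voxel_nm)
    res = _resolution_from_curve(freqs, fsc, threshold, voxel_nm)
    return FscResult(
        frequencies_per_nm=freqs, correlation=fsc, resolution_nm=res,
        threshold=threshold, n_half1=len(set1), n_half2=len(set2),
    )


@dataclass
class BlockwiseFsc:
    per_block: dict
    occupancy: dict
    mean_resolution_nm: float


def blockwise_fsc(locs: pd.DataFrame, block_nm: float = 1000.0,
                  min_locs: int = 1000, **fsc_kwargs) -> BlockwiseFsc:
    """FSC per cubic block of side ``block_nm``; only blocks holding more
    than ``min_locs`` localisations are analysed.  Returns the per-block
    results, a block occupancy map, and the mean block resolution (NaN when
    no block qualifies)."""
    xyz = locs[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    idx = np.floor(xyz / block_nm).astype(int)
    keys, inverse, counts = np.unique(idx, axis=0, return_inverse=True,
                                      return_counts=True)
    occupancy = {tuple(k): int(c) for k, c in zip(keys, counts)}
    per_block = {}
    for b, key in enumerate(keys):
        if counts[b] <= min_locs:
            continue
        sub = locs.iloc[np.nonzero(inverse == b)[0]]
        per_block[tuple(key)] = fsc_resolution(sub, **fsc_kwargs)
    if per_block:
        mean_res = float(np.mean([r.resolution_nm for r in per_block.values()]))
    else:
        log.warning("blockwise FSC: no block exceeds min_locs=%d", min_locs)
        mean_res = float("nan")
    return BlockwiseFsc(per_block=per_block, occupancy=occupancy,
                        mean_resolution_nm=mean_res)
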