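"""File dialects for DH-PSF analysis.

Image stacks are grayscale TIFFs; peak and localisation tables are CSV with
a header; calibration models are JSON; the ViSP export is a headerless
tab-separated ``x y z intensity frame`` file in nanometres.

Coordinate convention: 0-based pixel indices, ``x_px`` = column, ``y_px`` =
row; a peak at the centre of pixel (i, j) has ``x_px = j``, ``y_px = i``.
Physical position = coordinate x pixel size.  The pixel size is supplied by
the user (measured on the microscope with a grating target), never parsed
from TIFF tags.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

MODEL_FORMAT = "dhpsf-calibration"
MODEL_VERSION = 1

#: native peak-table schema (one row per fitted lobe)
PEAK_COLUMNS = ["frame", "x_px", "y_px", "intensity", "sigma_px", "background"]
MANDATORY_PEAK_COLUMNS = ["frame", "x_px", "y_px", "intensity"]

#: localisation-table schema (one row per paired molecule)
LOC_COLUMNS = [
    "frame", "x_nm", "y_nm", "z_nm", "intensity",
    "angle_deg", "interlobe_nm", "ratio", "kept", "reject_reason",
]

# Best-effort column-name mapping for tables exported by the external GDSC
# PeakFit fitter (case-insensitive).  This is a read-only dialect, not
# bit-exact compatibility with that tool's files.
GDSC_COLUMN_MAP = {
    "frame": "frame",
    "t": "frame",
    "x": "x_px",
    "origx": "x_px",
    "y": "y_px",
    "origy": "y_px",
    "signal": "intensity",
    "intensity": "intensity",
    "s": "sigma_px",
    "sd": "sigma_px",
    "background": "background",
    "bg": "background",
}


@dataclass
class ImageStack:
    """A multi-frame grayscale image stack with lateral pixel size metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)`` of intensity counts.
    pixel_size_nm
        Lateral pixel size in nanometres; must be positive.
    """

    frames: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, :, :]
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        if self.frames.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]


def read_image_stack(path, pixel_size_nm: float) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    Frames follow file page order.  RGB or multi-sample TIFFs are refused.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) == 0:
            raise ValueError(f"unsupported format: {path} contains zero pages")
        if tf.pages[0].samplesperpixel != 1:
            raise ValueError(
                f"unsupported format: {path} is not grayscale "
                f"(samples per pixel = {tf.pages[0].samplesperpixel})"
            )
        arr = tf.asarray()
    return ImageStack(frames=arr, pixel_size_nm=pixel_size_nm)


def write_image_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF, preserving dtype."""
    tifffile.imwrite(path, stack.frames, photometric="minisblack")


def _coerce_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric cell in column '{col}' of {path}") from exc
    return df


def read_peak_table(path, dialect: str = "native") -> pd.DataFrame:
    """Read a table of fitted 2D lobes.

    ``dialect='native'`` expects the :data:`PEAK_COLUMNS` header;
    ``dialect='gdsc'`` maps the external fitter's column names onto it.
    Rows are returned sorted by frame with coordinates in pixels.
    """
    if dialect not in ("native", "gdsc"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    if dialect == "gdsc":
        renames = {}
        for col in df.columns:
            key = str(col).strip().lower()
            if key in GDSC_COLUMN_MAP:
                target = GDSC_COLUMN_MAP[key]
                if target not in renames.values():
                    renames[col] = target
        df = df.rename(columns=renames)
    for col in MANDATORY_PEAK_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column '{col}' in {path}")
    for col in ("sigma_px", "background"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[PEAK_COLUMNS].copy()
    df = _coerce_numeric(df, PEAK_COLUMNS, path)
    df["frame"] = df["frame"].astype(int)
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    return df


def write_peak_table(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, index=False)


def read_localisation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("frame", "x_nm", "y_nm", "z_nm", "intensity"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column '{col}' in {path}")
    if "kept" not in df.columns:
        df["kept"] = True
    if "reject_reason" not in df.columns:
        df["reject_reason"] = "none"
    df["kept"] = df["kept"].astype(bool)
    df["frame"] = df["frame"].astype(int)
    return df


def write_localisation_table(locs: pd.DataFrame, path) -> None:
    locs.to_csv(path, index=False)


def write_visp(locs: pd.DataFrame, path) -> int:
    """Export kept localisations for the ViSP viewer.

    Tab-separated ``x_nm  y_nm  z_nm  intensity  frame``, no header, one row
    per kept localisation.  Returns the number of rows written; an empty
    (all-rejected) table yields an empty file and a logged warning.
    """
    kept = locs[locs["kept"]] if "kept" in locs.columns else locs
    lines = []
    for row in kept.itertuples(index=False):
        lines.append(
            f"{float(row.x_nm)}\t{float(row.y_nm)}\t{float(row.z_nm)}\t"
            f"{float(row.intensity)}\t{int(row.frame)}"
        )
    if not lines:
        log.warning("ViSP export: no kept localisations, writing empty file %s", path)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return len(lines)


def save_model(model, path) -> None:
    """Serialise a calibration model to human-readable JSON."""
    payload = {"format": MODEL_FORMAT, "version": MODEL_VERSION}
    payload.update(model.to_dict())
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path):
    """Load a calibration model saved by :func:`save_model`."""
    from .calibrate import CalibrationModel

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model file {path}: {exc}") from exc
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"malformed model file {path}: not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise ValueError(
            f"model file version mismatch in {path}: "
            f"got {payload.get('version')}, expected {MODEL_VERSION}"
        )
    for key in ("degree", "theta_range", "pixel_size_nm", "curves"):
        if key not in payload:
            raise ValueError(f"malformed model file {path}: missing '{key}'")
    return CalibrationModel.from_dict(payload)
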