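"""Localization-table data model, I/O, grouping, drift correction and image reconstruction.

Single-molecule localization microscopy (SMLM) data arrive as tables with one
row per detected fluorophore blink: position (nm), acquisition frame, channel
label, and optionally the localization precision.  This module holds the
canonical in-memory representation (:class:`LocalizationTable`, a thin wrapper
around a :class:`pandas.DataFrame`), binary region-of-interest masks
(:class:`RoiMask`), and the standard preprocessing steps that sit upstream of
any correlation analysis:

* merging of sequential-frame re-detections of the same emitter
  (:func:`group_sequential`, default 80 nm radius),
* stage-drift correction from block-wise image cross-correlation
  (:func:`correct_drift`, default 500-frame blocks),
* reconstruction of localization-count images on a 25 nm pixel grid
  (:func:`reconstruct_image`).

Coordinates are continuous nanometres with the origin at the lower-left corner
of the field of view; rasters use half-open pixel bins ``[k*p, (k+1)*p)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("x_nm", "y_nm", "frame", "channel")
OPTIONAL_COLUMNS = ("sigma_nm", "cell_id", "molecule_id", "disc_id", "burst_id")

#: Column mapping for ThunderSTORM-style exports (positions in micrometres).
_THUNDERSTORM_MAP = {
    "x [um]": "x_nm",
    "y [um]": "y_nm",
    "frame": "frame",
    "channel": "channel",
    "uncertainty [um]": "sigma_nm",
}


class FormatError(ValueError):
    """Raised when an input file does not carry the required columns."""


class ValidationError(ValueError):
    """Raised when table contents violate the data-model invariants."""


class LocalizationTable:
    """Point-pattern record of single-molecule detections.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain ``x_nm, y_nm, frame, channel``; extra columns (ground
        truth ids from the synthetic generators, per-localization precision)
        are carried along.
    grouped : bool
        Whether sequential-frame re-detections have already been merged.
    """

    def __init__(self, data: pd.DataFrame, grouped: bool = False, validate: bool = True):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        self.data = data.reset_index(drop=True)
        self.grouped = bool(grouped)
        if validate:
            self.validate()

    # -- construction helpers ------------------------------------------------
    @classmethod
    def from_arrays(cls, x, y, frame, channel, grouped=False, **extra) -> "LocalizationTable":
        n = len(np.atleast_1d(x))
        cols = {
            "x_nm": np.asarray(x, dtype=float),
            "y_nm": np.asarray(y, dtype=float),
            "frame": np.asarray(frame, dtype=np.int64),
            "channel": np.broadcast_to(np.asarray(channel, dtype=object), (n,)).copy(),
        }
        for k, v in extra.items():
            cols[k] = np.broadcast_to(np.asarray(v), (n,)).copy()
        return cls(pd.DataFrame(cols), grouped=grouped)

    def validate(self) -> None:
        d = self.data
        if len(d):
            xy = d[["x_nm", "y_nm"]].to_numpy(dtype=float)
            if not np.all(np.isfinite(xy)):
                raise ValidationError("non-finite coordinates")
            frames = d["frame"].to_numpy()
            if not np.issubdtype(frames.dtype, np.integer):
                if not np.allclose(frames, np.round(frames)):
                    raise ValidationError("frame indices must be integers")
                d["frame"] = frames = np.round(frames).astype(np.int64)
            if frames.min() < 0:
                raise ValidationError("negative frame index")

    # -- basic protocol ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def x(self) -> np.ndarray:
        return self.data["x_nm"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["y_nm"].to_numpy(dtype=float)

    @property
    def frame(self) -> np.ndarray:
        return self.data["frame"].to_numpy(dtype=np.int64)

    @property
    def channels(self) -> list:
        return sorted(map(str, self.data["channel"].unique()))

    def select_channel(self, channel) -> "LocalizationTable":
        sub = self.data[self.data["channel"].astype(str) == str(channel)]
        return LocalizationTable(sub.copy(), grouped=self.grouped, validate=False)

    def canonical_sort(self) -> "LocalizationTable":
        """Sort by (channel, frame); stable and idempotent."""
        d = self.data.sort_values(["channel", "frame"], kind="stable")
        return LocalizationTable(d.reset_index(drop=True), grouped=self.grouped, validate=False)

    def shifted(self, dx: float, dy: float) -> "LocalizationTable":
        d = self.data.copy()
        d["x_nm"] = d["x_nm"] + dx
        d["y_nm"] = d["y_nm"] + dy
        return LocalizationTable(d, grouped=self.grouped, validate=False)

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path, include_ground_truth: bool = False) -> None:
        cols = [c for c in REQUIRED_COLUMNS if c in self.data.columns]
        extra = ["sigma_nm", "cell_id"] if not include_ground_truth else list(OPTIONAL_COLUMNS)
        cols += [c for c in extra if c in self.data.columns]
        self.data[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dialect: str = "native") -> "LocalizationTable":
        return read_localizations(path, dialect=dialect)

    def to_hdf5(self, path) -> None:
        """Compact storage for large (live-stream) tables."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["grouped"] = self.grouped
            f.create_dataset("x_nm", data=self.x)
            f.create_dataset("y_nm", data=self.y)
            f.create_dataset("frame", data=self.frame)
            f.create_dataset(
                "channel", data=np.asarray(self.data["channel"], dtype="S32")
            )
            if "sigma_nm" in self.data.columns:
                f.create_dataset("sigma_nm", data=self.data["sigma_nm"].to_numpy(float))

    @classmethod
    def from_hdf5(cls, path) -> "LocalizationTable":
        import h5py

        with h5py.File(path, "r") as f:
            cols = {
                "x_nm": f["x_nm"][:],
                "y_nm": f["y_nm"][:],
                "frame": f["frame"][:],
                "channel": f["channel"][:].astype(str),
            }
            if "sigma_nm" in f:
                cols["sigma_nm"] = f["sigma_nm"][:]
            grouped = bool(f.attrs.get("grouped", False))
        return cls(pd.DataFrame(cols), grouped=grouped)


def read_localizations(path, dialect: str = "native") -> LocalizationTable:
    """Read a localization table from CSV.

    ``dialect='native'`` expects nm-unit columns ``x_nm, y_nm, frame, channel``;
    ``dialect='thunderstorm'`` accepts micrometre columns (``x [um]`` ...) and
    converts them to nm.  An empty file yields an empty table with a warning.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty localization file: {path}")
        raw = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    if dialect == "native":
        df = raw
    elif dialect == "thunderstorm":
        missing = [c for c in ("x [um]", "y [um]", "frame") if c not in raw.columns]
        if missing:
            raise FormatError(f"ThunderSTORM dialect: missing columns {missing}")
        df = pd.DataFrame()
        for src, dst in _THUNDERSTORM_MAP.items():
            if src in raw.columns:
                df[dst] = raw[src]
        for col in ("x_nm", "y_nm", "sigma_nm"):
            if col in df.columns:
                df[col] = df[col].astype(float) * 1000.0  # um -> nm
        if "channel" not in df.columns:
            df["channel"] = "ch1"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    n_bad = int(df[["x_nm", "y_nm"]].isna().any(axis=1).sum()) if len(df) else 0
    if n_bad:
        logger.warning("dropping %d malformed rows from %s", n_bad, path)
        df = df[~df[["x_nm", "y_nm"]].isna().any(axis=1)]
    return LocalizationTable(df.reset_index(drop=True))


@dataclass
class RoiMask:
    """Binary region-of-interest raster on the analysis pixel grid."""

    mask: np.ndarray  # bool, shape (ny, nx); row 0 = lowest y
    pixel_size: float = 25.0  # nm
    origin: tuple = (0.0, 0.0)  # nm offset of pixel (0, 0) lower-left corner

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def area_nm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size**2

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    @classmethod
    def rectangle(cls, width_nm: float, height_nm: float, pixel_size: float = 25.0) -> "RoiMask":
        nx = int(np.ceil(width_nm / pixel_size))
        ny = int(np.ceil(height_nm / pixel_size))
        return cls(np.ones((ny, nx), dtype=bool), pixel_size=pixel_size)

    def pixel_indices(self, x: np.ndarray, y: np.ndarray):
        """Map nm coordinates to (row, col) with half-open pixel bins."""
        col = np.floor((np.asarray(x, float) - self.origin[0]) / self.pixel_size).astype(np.int64)
        row = np.floor((np.asarray(y, float) - self.origin[1]) / self.pixel_size).astype(np.int64)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.pixel_indices(x, y)
        ny, nx = self.mask.shape
        ok = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
        out = np.zeros(len(np.atleast_1d(x)), dtype=bool)
        out[ok] = self.mask[row[ok], col[ok]]
        return out

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.mask.astype(np.uint8))

    @classmethod
    def from_tiff(cls, path, pixel_size: float = 25.0) -> "RoiMask":
        return cls(tifffile.imread(path) > 0, pixel_size=pixel_size)


@dataclass
class ReconstructedImage:
    """Localization-count raster (sum of raster = number of rendered points)."""

    counts: np.ndarray
    pixel_size: float = 25.0
    channel: str = ""
    grouped: bool = False

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def reconstruct_image(
    locs: LocalizationTable,
    mask: RoiMask,
    pixel_size: float | None = None,
    channel: str | None = None,
) -> ReconstructedImage:
    """Render in-mask localizations into a count image on the mask's grid.

    Out-of-mask localizations are excluded so the raster sum equals the
    in-mask localization count.
    """
    if pixel_size is not None and pixel_size != mask.pixel_size:
        raise ValueError("pixel_size must match the mask grid")
    if pixel_size is not None and pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if channel is not None:
        locs = locs.select_channel(channel)
    ny, nx = mask.shape
    row, col = mask.pixel_indices(locs.x, locs.y)
    ok = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
    ok[ok] &= mask.mask[row[ok], col[ok]]
    counts = np.zeros((ny, nx), dtype=np.float64)
    np.add.at(counts, (row[ok], col[ok]), 1.0)
    return ReconstructedImage(
        counts, pixel_size=mask.pixel_size, channel=channel or "", grouped=locs.grouped
    )


def group_sequential(locs: LocalizationTable, radius: float = 80.0) -> LocalizationTable:
    """Merge chains of sequential-frame re-detections of one emitter.

    Localizations appearing within ``radius`` (nm) of an open chain's running
    mean position in the immediately following frame are merged into that
    chain; the chain is emitted as a single localization at the chain mean
    with the first frame index.  Re-appearances after a frame gap start a new
    chain (reversible photo-activation is *not* corrected by grouping).
    """
    if radius <= 0:
        raise ValueError("grouping radius must be positive")
    out_frames = []
    for ch in locs.channels:
        sub = locs.select_channel(ch).canonical_sort()
        d = sub.data
        x, y, fr = d["x_nm"].to_numpy(), d["y_nm"].to_numpy(), d["frame"].to_numpy()
        n = len(d)
        # open chains: list of [sum_x, sum_y, count, first_frame, first_row]
        merged_rows = np.empty(n, dtype=np.int64)
        gx = np.empty(n)
        gy = np.empty(n)
        gframe = np.empty(n, dtype=np.int64)
        n_out = 0
        open_chains: list[list] = []  # chains reachable from the current frame
        prev_frame = None
        i = 0
        while i <= n:
            f = fr[i] if i < n else None
            if f != prev_frame:
                # close chains that did not extend into the previous frame
                still_open = []
                for c in open_chains:
                    if prev_frame is not None and f is not None and c[5] == prev_frame and f == prev_frame + 1:
                        still_open.append(c)
                    else:
                        gx[n_out] = c[0] / c[2]
                        gy[n_out] = c[1] / c[2]
                        gframe[n_out] = c[3]
                        merged_rows[n_out] = c[4]
                        n_out += 1
                open_chains = still_open
                prev_frame = f
            if i == n:
                break
            # try to attach localization i to the nearest open chain
            best = None
            best_d2 = radius * radius
            for c in open_chains:
                if c[5] == f:  # chain already extended in this frame
                    continue
                mx, my = c[0] / c[2], c[1] / c[2]
                d2 = (x[i] - mx) ** 2 + (y[i] - my) ** 2
                if d2 <= best_d2:
                    best, best_d2 = c, d2
            if best is not None:
                best[0] += x[i]
                best[1] += y[i]
                best[2] += 1
                best[5] = f
            else:
                open_chains.append([x[i], y[i], 1, f, i, f])
            i += 1
        keep = d.iloc[merged_rows[:n_out]].copy()
        keep["x_nm"] = gx[:n_out]
        keep["y_nm"] = gy[:n_out]
        keep["frame"] = gframe[:n_out]
        out_frames.append(keep)
    out = pd.concat(out_frames, ignore_index=True) if out_frames else locs.data.iloc[:0].copy()
    return LocalizationTable(out, grouped=True, validate=False).canonical_sort()


@dataclass
class DriftTrace:
    """Per-frame drift estimate (nm), as subtracted from the localizations."""

    frame: np.ndarray
    dx_nm: np.ndarray
    dy_nm: np.ndarray
    block_frames: np.ndarray = field(default_factory=lambda: np.array([]))
    block_dx: np.ndarray = field(default_factory=lambda: np.array([]))
    block_dy: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_csv(self, path) -> None:
        pd.DataFrame({"frame": self.frame, "dx_nm": self.dx_nm, "dy_nm": self.dy_nm}).to_csv(
            path, index=False
        )


def _subpixel_argmax(corr: np.ndarray) -> tuple:
    """Argmax of a correlation surface with 3x3 parabolic refinement."""
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    ny, nx = corr.shape

    def _refine(vm, v0, vp):
        denom = vm - 2.0 * v0 + vp
        if denom >= 0 or abs(denom) < 1e-300:
            return 0.0
        return float(np.clip(0.5 * (vm - vp) / denom, -0.5, 0.5))

    dy = dx = 0.0
    if 0 < iy < ny - 1:
        dy = _refine(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    if 0 < ix < nx - 1:
        dx = _refine(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    return iy + dy, ix + dx


def _block_shift(ref_img: np.ndarray, img: np.ndarray, pixel_size: float) -> tuple:
    """Shift of ``img`` relative to ``ref_img`` via FFT cross-correlation (nm).

    Block images are lightly smoothed (sigma = 1 px) before correlating so the
    sparse-count correlation peak is wide enough for the 3x3 parabolic
    sub-pixel refinement.
    """
    from scipy import ndimage

    ref_img = ndimage.gaussian_filter(ref_img, 1.0)
    img = ndimage.gaussian_filter(img, 1.0)
    ny, nx = ref_img.shape
    fa = np.fft.rfft2(ref_img, s=(2 * ny, 2 * nx))
    fb = np.fft.rfft2(img, s=(2 * ny, 2 * nx))
    corr = np.fft.irfft2(fa.conj() * fb, s=(2 * ny, 2 * nx))
    corr = np.fft.fftshift(corr)
    py, px = _subpixel_argmax(corr)
    # center of the shifted array corresponds to zero lag
    return (px - nx) * pixel_size, (py - ny) * pixel_size


def correct_drift(
    locs: LocalizationTable,
    block: int = 500,
    pixel_size: float = 25.0,
    min_per_block: int = 50,
) -> tuple:
    """Estimate and subtract stage drift from block-wise image correlation.

    Localizations are split into ``block``-frame groups; each group is
    reconstructed on a ``pixel_size`` raster and the shift of every block
    relative to the first is found as the (sub-pixel, 3x3-parabolic) argmax
    of the 2D cross-correlation between block images.  Shifts are assigned to
    block-midpoint frames, linearly interpolated per frame (nearest-block
    beyond the first/last midpoints) and subtracted.

    Returns
    -------
    (LocalizationTable, DriftTrace)
    """
    fr = locs.frame
    if len(fr) == 0:
        raise ValidationError("empty localization table")
    f0, f1 = int(fr.min()), int(fr.max())
    n_blocks = int(np.ceil((f1 - f0 + 1) / block))
    if n_blocks < 2:
        raise ValidationError("need at least two blocks of frames for drift correction")
    x, y = locs.x, locs.y
    pad = 2 * pixel_size
    extent = (x.min() - pad, x.max() + pad, y.min() - pad, y.max() + pad)
    nx = int(np.ceil((extent[1] - extent[0]) / pixel_size))
    ny = int(np.ceil((extent[3] - extent[2]) / pixel_size))
    block_ids = ((fr - f0) // block).astype(int)
    images = np.zeros((n_blocks, ny, nx))
    counts = np.bincount(block_ids, minlength=n_blocks)
    col = np.floor((x - extent[0]) / pixel_size).astype(int)
    row = np.floor((y - extent[2]) / pixel_size).astype(int)
    np.add.at(images, (block_ids, row, col), 1.0)
    # shifts between successive blocks, then accumulated relative to block 0
    steps = np.full((n_blocks, 2), np.nan)
    steps[0] = 0.0
    last_good = 0
    for b in range(1, n_blocks):
        if counts[b] < min_per_block:
            logger.warning("drift block %d has %d localizations; interpolating", b, counts[b])
            continue
        steps[b] = _block_shift(images[last_good], images[b], pixel_size)
        last_good = b
    shifts = np.zeros((n_blocks, 2))
    for axis in range(2):
        s = steps[:, axis]
        good = np.isfinite(s)
        acc = np.cumsum(np.where(good, s, 0.0))
        # skipped blocks: interpolate the accumulated trace from neighbors
        shifts[:, axis] = np.interp(
            np.arange(n_blocks), np.flatnonzero(good), acc[good]
        )
    mid = f0 + (np.arange(n_blocks) + 0.5) * block
    frames = np.arange(f0, f1 + 1)
    dx = np.interp(frames, mid, shifts[:, 0])
    dy = np.interp(frames, mid, shifts[:, 1])
    d = locs.data.copy()
    d["x_nm"] = d["x_nm"] - dx[fr - f0]
    d["y_nm"] = d["y_nm"] - dy[fr - f0]
    trace = DriftTrace(frames, dx, dy, mid, shifts[:, 0], shifts[:, 1])
    return LocalizationTable(d, grouped=locs.grouped, validate=False), trace
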