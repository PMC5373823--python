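"""Steady-state cross-correlation and single-particle step analysis for live cells.

Live-cell SMLM streams resolve localizations per frame.  Because probes
diffuse, the instantaneous cross-correlation between two channels is poorly
sampled in any single frame; when the correlation does not decay over a short
time-delay window (here up to 50 frames, ~1 s) the frame-pair correlations can
be averaged into a *steady-state* cross-correlation.  Live data additionally
carry >1 um labeling-density gradients (probes diffusing in from the dorsal
membrane are less bleached near the cell edge), which are removed by dividing
by the cross-correlation of the two channels' average images after blurring
with a sigma = 1 um Gaussian — a high-pass filter passing only sub-micron
structure.

The tracking utilities build conservative single-molecule trajectories
(greedy nearest-neighbor linking within 500 nm, terminating any ambiguous
assignment) and compare step-size distributions of reference-proximal probe
localizations (within 100 nm of a simultaneous reference localization)
against the full population, which detects binding-induced mobility changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, spatial, stats

from .loc_data import LocalizationTable, ReconstructedImage, RoiMask, reconstruct_image
from .pair_correlation import (
    CorrelationResult,
    _cross_corr2d,
    _mask_autocorr,
    _radial_result,
)

__all__ = [
    "SteadyStateCorr",
    "TrackSet",
    "steadystate_crosscorr",
    "link_tracks",
    "step_sizes",
    "correlated_steps",
    "msd_diffusion_coefficient",
]


@dataclass
class SteadyStateCorr:
    """Per-tau and tau-averaged steady-state cross-correlation curves."""

    taus: np.ndarray
    per_tau: list  # CorrelationResult per tau (before long-range normalization)
    averaged: CorrelationResult  # tau-averaged, normalized curve
    norm_curve: np.ndarray  # long-range normalization divisor per bin
    meta: dict = field(default_factory=dict)


def _frame_images(locs: LocalizationTable, mask: RoiMask, frames: np.ndarray) -> dict:
    imgs = {}
    d = locs.data
    for f, sub in d.groupby("frame"):
        t = LocalizationTable(sub, grouped=locs.grouped, validate=False)
        imgs[int(f)] = reconstruct_image(t, mask).counts
    return imgs


def steadystate_crosscorr(
    locs_a: LocalizationTable,
    locs_b: LocalizationTable,
    mask: RoiMask,
    tau_max: int = 50,
    dr: float = 25.0,
    r_max: float = 1000.0,
    norm_blur_nm: float = 1000.0,
) -> SteadyStateCorr:
    """Tau-averaged frame-pair cross-correlation with >1 um structure removed.

    For each time delay tau in 0..tau_max, pair counts are accumulated over
    all frame pairs (f, f+tau) in both channel orders and normalized by the
    mask autocorrelation and the per-pair channel totals.  The per-tau curves
    are averaged with equal weight, then divided by the cross-correlation of
    the two channels' masked average images blurred with a truncated (+/- 4
    sigma) Gaussian of ``norm_blur_nm``.
    """
    fa = locs_a.frame
    fb = locs_b.frame
    fmin = int(min(fa.min(), fb.min()))
    fmax = int(max(fa.max(), fb.max()))
    n_frames = fmax - fmin + 1
    if tau_max >= n_frames:
        warnings.warn("tau_max exceeds the stream length; truncating")
        tau_max = n_frames - 1
    imgs_a = _frame_images(locs_a, mask, None)
    imgs_b = _frame_images(locs_b, mask, None)
    ny, nx = mask.shape
    shape = (2 * ny, 2 * nx)
    f_a, f_b, n_a, n_b = {}, {}, {}, {}
    for f, img in imgs_a.items():
        m = img * mask.mask
        f_a[f] = np.fft.rfft2(m, s=shape)
        n_a[f] = float(m.sum())
    for f, img in imgs_b.items():
        m = img * mask.mask
        f_b[f] = np.fft.rfft2(m, s=shape)
        n_b[f] = float(m.sum())
    maskcorr = _mask_autocorr(mask.mask, periodic=False)
    mask_px = float(mask.mask.sum())
    taus = np.arange(tau_max + 1)
    per_tau = []
    for tau in taus:
        spec = None
        pairsum = 0.0
        for f, ffa in f_a.items():
            for g in ({f + tau, f - tau} if tau else {f}):
                if g in f_b:
                    term = np.conj(ffa) * f_b[g]
                    spec = term if spec is None else spec + term
                    pairsum += n_a[f] * n_b[g]
        if spec is None or pairsum == 0:
            per_tau.append(None)
            continue
        cross = np.fft.fftshift(np.fft.irfft2(spec, s=shape))
        meta = {"tau": int(tau), "N1": np.nan, "N2": np.nan, "periodic": False,
                "pixel_size": mask.pixel_size}
        res = _radial_result(
            cross, maskcorr, np.sqrt(pairsum), np.sqrt(pairsum), mask_px,
            mask.pixel_size, dr, r_max, meta,
        )
        per_tau.append(res)
    usable = [res for res in per_tau if res is not None]
    if not usable:
        raise ValueError("no overlapping frame pairs between channels")
    edges = usable[0].r_edges
    stack = np.vstack([res.c for res in usable])
    c_avg = np.nanmean(stack, axis=0)
    counts = np.sum([res.counts for res in usable], axis=0)
    expected = np.sum([res.expected for res in usable], axis=0)
    sem = (
        np.nanstd(stack, axis=0, ddof=1) / np.sqrt(len(usable))
        if len(usable) > 1
        else np.full_like(c_avg, np.nan)
    )
    # long-range normalization: correlation of blurred average images
    avg_a = np.sum([imgs_a[f] for f in imgs_a], axis=0) * mask.mask
    avg_b = np.sum([imgs_b[f] for f in imgs_b], axis=0) * mask.mask
    spx = norm_blur_nm / mask.pixel_size
    blur_a = ndimage.gaussian_filter(avg_a, spx, truncate=4.0)
    blur_b = ndimage.gaussian_filter(avg_b, spx, truncate=4.0)
    blur_a *= mask.mask
    blur_b *= mask.mask
    norm_res = _radial_result(
        _cross_corr2d(blur_a, blur_b, False),
        maskcorr,
        float(blur_a.sum()),
        float(blur_b.sum()),
        mask_px,
        mask.pixel_size,
        dr,
        r_max,
        {"periodic": False, "pixel_size": mask.pixel_size},
    )
    norm = norm_res.c
    with np.errstate(divide="ignore", invalid="ignore"):
        c_final = np.where(norm > 0, c_avg / np.where(norm > 0, norm, 1.0), np.nan)
    averaged = CorrelationResult(
        edges,
        counts,
        expected,
        c_final,
        sem,
        meta={
            "tau_max": int(tau_max),
            "norm_blur_nm": norm_blur_nm,
            "pixel_size": mask.pixel_size,
            "c_unnormalized": c_avg,
        },
    )
    return SteadyStateCorr(taus, per_tau, averaged, norm, {"n_frames": n_frames})


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


@dataclass
class TrackSet:
    """Single-molecule trajectories from conservative frame-to-frame linking."""

    tracks: pd.DataFrame  # columns track_id, frame, x_nm, y_nm
    linking_radius_nm: float
    frame_interval_s: float = np.nan

    @property
    def n_tracks(self) -> int:
        return int(self.tracks["track_id"].nunique())

    def to_csv(self, path) -> None:
        self.tracks[["track_id", "frame", "x_nm", "y_nm"]].to_csv(path, index=False)

    def steps(self) -> np.ndarray:
        """Frame-to-frame displacements (nm) pooled over all trajectories."""
        out = []
        for _, t in self.tracks.groupby("track_id"):
            xy = t.sort_values("frame")[["x_nm", "y_nm"]].to_numpy()
            if len(xy) > 1:
                out.append(np.hypot(*np.diff(xy, axis=0).T))
        return np.concatenate(out) if out else np.empty(0)

    def displacements(self, lag: int) -> np.ndarray:
        out = []
        for _, t in self.tracks.groupby("track_id"):
            xy = t.sort_values("frame")[["x_nm", "y_nm"]].to_numpy()
            if len(xy) > lag:
                out.append(np.hypot(*(xy[lag:] - xy[:-lag]).T))
        return np.concatenate(out) if out else np.empty(0)


def link_tracks(
    locs: LocalizationTable,
    max_step: float = 500.0,
    frame_interval_s: float = np.nan,
) -> TrackSet:
    """Greedy frame-to-frame linking that terminates ambiguous trajectories.

    A trajectory head is extended only when exactly one localization in the
    next frame lies within ``max_step`` of it AND that localization is claimed
    by no other head; any ambiguity (two candidates for one head, or two heads
    competing for one candidate) terminates all trajectories involved, and the
    contested localizations start fresh trajectories.  No localization is
    assigned to two trajectories, and no recorded step exceeds ``max_step``.
    """
    if len(locs.data["channel"].unique()) > 1:
        raise ValueError("link_tracks expects a single-channel table")
    d = locs.canonical_sort().data
    frames = d["frame"].to_numpy()
    xy = d[["x_nm", "y_nm"]].to_numpy(dtype=float)
    track_id = np.full(len(d), -1, dtype=np.int64)
    next_id = 0
    # active heads: row index -> track id
    head_rows: np.ndarray = np.empty(0, dtype=np.int64)
    unique_frames = np.unique(frames)
    row_by_frame = {f: np.flatnonzero(frames == f) for f in unique_frames}
    prev_f = None
    for f in unique_frames:
        rows = row_by_frame[f]
        if prev_f is None or f != prev_f + 1 or len(head_rows) == 0:
            # gap in frames: all trajectories terminate
            for r in rows:
                track_id[r] = next_id
                next_id += 1
            head_rows = rows
            prev_f = f
            continue
        tree_new = spatial.cKDTree(xy[rows])
        cand = tree_new.query_ball_point(xy[head_rows], max_step)
        claims = np.zeros(len(rows), dtype=np.int64)
        for c in cand:
            for j in c:
                claims[j] += 1
        new_heads = []
        linked_new = np.zeros(len(rows), dtype=bool)
        for hi, c in enumerate(cand):
            if len(c) == 1 and claims[c[0]] == 1:
                j = c[0]
                track_id[rows[j]] = track_id[head_rows[hi]]
                linked_new[j] = True
                new_heads.append(rows[j])
            # else: ambiguous or no candidate -> trajectory terminates here
        for j in np.flatnonzero(~linked_new):
            track_id[rows[j]] = next_id
            next_id += 1
            new_heads.append(rows[j])
        head_rows = np.asarray(new_heads, dtype=np.int64)
        prev_f = f
    out = d.copy()
    out["track_id"] = track_id
    return TrackSet(
        out[["track_id", "frame", "x_nm", "y_nm"]].reset_index(drop=True),
        linking_radius_nm=max_step,
        frame_interval_s=frame_interval_s,
    )


@dataclass
class StepDistribution:
    """Empirical per-frame step-size distribution (cumulative form on demand)."""

    steps_nm: np.ndarray
    label: str = ""

    def cumulative(self, s_grid: np.ndarray | None = None) -> tuple:
        s = np.sort(self.steps_nm)
        if s_grid is None:
            return s, np.arange(1, len(s) + 1) / max(len(s), 1)
        return s_grid, np.searchsorted(s, s_grid, side="right") / max(len(s), 1)

    def __len__(self):
        return len(self.steps_nm)


def step_sizes(tracks: TrackSet) -> StepDistribution:
    """Pooled per-frame displacement distribution over all trajectories.

    For Brownian motion with diffusion coefficient D, frame interval dt and
    localization noise sigma, step sizes follow the Rayleigh-type law
    CDF(s) = 1 - exp(-s^2 / (4 D dt + 4 sigma^2)).
    """
    return StepDistribution(tracks.steps(), label="all steps")


def correlated_steps(
    tracks_probe: TrackSet,
    locs_ref: LocalizationTable,
    radius: float = 100.0,
) -> StepDistribution:
    """Steps of probe localizations proximal to a simultaneous reference.

    A probe trajectory point within ``radius`` of any same-frame reference
    localization contributes the steps to its immediately preceding and
    following trajectory points.  The result is a sub-multiset of the full
    step distribution; an empty subset is returned flagged (label) when no
    proximal instance exists.
    """
    ref_by_frame = {
        int(f): spatial.cKDTree(sub[["x_nm", "y_nm"]].to_numpy())
        for f, sub in locs_ref.data.groupby("frame")
    }
    out = []
    for _, t in tracks_probe.tracks.groupby("track_id"):
        t = t.sort_values("frame")
        xy = t[["x_nm", "y_nm"]].to_numpy()
        fr = t["frame"].to_numpy()
        if len(t) < 2:
            continue
        for i in range(len(t)):
            tree = ref_by_frame.get(int(fr[i]))
            if tree is None:
                continue
            if tree.query_ball_point(xy[i], radius, return_length=True) == 0:
                continue
            if i > 0:
                out.append(np.hypot(*(xy[i] - xy[i - 1])))
            if i < len(t) - 1:
                out.append(np.hypot(*(xy[i + 1] - xy[i])))
    if not out:
        warnings.warn("no reference-proximal probe localizations")
    return StepDistribution(np.asarray(out), label=f"steps within {radius:g} nm of reference")


def msd_diffusion_coefficient(
    tracks: TrackSet,
    frame_interval_s: float | None = None,
    max_lag: int = 4,
) -> dict:
    """Diffusion coefficient from a linear MSD fit.

    MSD(n dt) = 4 D n dt + 4 sigma_loc^2 for 2D Brownian motion with static
    localization noise; the slope of a linear fit over lags 1..``max_lag``
    gives D (um^2/s) and the intercept the noise term.
    """
    if frame_interval_s is None:
        frame_interval_s = tracks.frame_interval_s
    if not np.isfinite(frame_interval_s):
        raise ValueError("frame interval required")
    lags = np.arange(1, max_lag + 1)
    msd = np.array([np.mean(tracks.displacements(int(n)) ** 2) for n in lags])  # nm^2
    slope, intercept = np.polyfit(lags * frame_interval_s, msd, 1)
    d_um2_s = slope / 4.0 * 1e-6  # nm^2/s -> um^2/s
    sigma_loc = np.sqrt(max(intercept, 0.0) / 4.0)
    return {"D_um2_s": float(d_um2_s), "sigma_loc_nm": float(sigma_loc),
            "msd_nm2": msd, "lags": lags}


def ks_compare(a: StepDistribution, b: StepDistribution) -> dict:
    """Two-sample KS test between step distributions."""
    stat, p = stats.ks_2samp(a.steps_nm, b.steps_nm)
    return {"statistic": float(stat), "pvalue": float(p), "n_a": len(a), "n_b": len(b)}
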