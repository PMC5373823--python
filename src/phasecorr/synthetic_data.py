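"""Ground-truth scene generation and sampling into localization tables.

Every downstream stage of the package is testable without experimental data
because this module emulates the statistical structure of two-color fixed-cell
SMLM acquisitions and live-cell localization streams:

* molecule layouts — random, clustered in one channel, independently
  clustered in both channels, or co-clustered (shared disc centers), with
  non-overlapping discs placed by rejection sampling;
* blinking/overcounting — each molecule is observed a Poisson number of times
  (target 10-50 observations over 5000-10,000 frames), optionally organised
  into consecutive-frame bursts with geometric lengths, each observation
  displaced by isotropic Gaussian localization noise (default 30 nm);
* lattice-simulation scenes — a species raster from the Ising simulator is
  sampled into point channels at a chosen probe density, with optional
  Gaussian blur, to bridge simulations to the correlation analysis;
* ROI topology — masks with probe-free holes reproducing the long-range
  correlation artifact of membrane regions detached from the coverslip;
* live streams — 2D Brownian motion with per-frame localizations and an
  optional transiently-bound sub-population near reference points.

Ground-truth identifiers (molecule id, disc id, burst id) travel with every
sampled table so tests can join localizations back to the generating truth.
All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .loc_data import LocalizationTable, RoiMask

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "BlinkModel",
    "BindingSpec",
    "PackingError",
    "generate_scene",
    "sample_localizations",
    "sample_ising_scene",
    "generate_topology_mask",
    "generate_live_stream",
]

CLUSTER_MODES = ("random", "clustered_one_channel", "clustered_both_independent", "co_clustered")


class PackingError(RuntimeError):
    """Disc packing infeasible within the attempt budget."""


@dataclass
class SceneSpec:
    """Recipe for a ground-truth molecule scene.

    ``density_um2`` applies per channel in ``random`` mode (Poisson counts);
    in clustered modes molecules come as ``n_discs`` x ``molecules_per_disc``
    per clustered channel, and unclustered channels fall back to
    ``density_um2``.
    """

    mode: str = "random"
    fov_nm: tuple = (10000.0, 10000.0)
    density_um2: float = 10.0
    n_discs: int = 20
    disc_radius_nm: float = 50.0
    molecules_per_disc: int = 10
    channels: tuple = ("a", "b")
    seed: int = 0
    max_attempts: int = 100_000

    def __post_init__(self):
        if self.mode not in CLUSTER_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fov_nm[0] <= 0 or self.fov_nm[1] <= 0:
            raise ValueError("field of view area must be positive")


@dataclass
class SyntheticScene:
    """Ground-truth molecule positions per channel, with disc bookkeeping."""

    spec: SceneSpec
    positions: dict  # channel -> (n, 2) nm
    disc_ids: dict  # channel -> (n,) int, -1 for non-disc molecules
    disc_centers: dict  # channel -> (n_discs, 2) nm

    @property
    def fov_nm(self) -> tuple:
        return self.spec.fov_nm


def _pack_discs(rng, fov, n, radius, max_attempts) -> np.ndarray:
    """Place n non-overlapping discs (center distance > 2 radius) in fov."""
    if 2 * radius > min(fov):
        raise PackingError("disc diameter exceeds the field of view")
    centers = np.empty((n, 2))
    placed = 0
    for _ in range(max_attempts):
        if placed == n:
            break
        cand = np.array([rng.uniform(radius, fov[0] - radius), rng.uniform(radius, fov[1] - radius)])
        if placed and np.min(np.hypot(*(centers[:placed] - cand).T)) <= 2 * radius:
            continue
        centers[placed] = cand
        placed += 1
    if placed < n:
        raise PackingError(f"placed {placed}/{n} discs in {max_attempts} attempts")
    return centers


def _fill_disc(rng, center, radius, n) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    return center + np.column_stack([r * np.cos(th), r * np.sin(th)])


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Build a ground-truth scene per ``spec``; deterministic in (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    fov = spec.fov_nm
    area_um2 = fov[0] * fov[1] * 1e-6
    positions, disc_ids, disc_centers = {}, {}, {}

    def _random_channel():
        n = rng.poisson(spec.density_um2 * area_um2)
        pos = np.column_stack([rng.uniform(0, fov[0], n), rng.uniform(0, fov[1], n)])
        return pos, np.full(n, -1, dtype=np.int64), np.empty((0, 2))

    def _clustered_channel(centers):
        pos = np.vstack(
            [_fill_disc(rng, c, spec.disc_radius_nm, spec.molecules_per_disc) for c in centers]
        ) if len(centers) else np.empty((0, 2))
        ids = np.repeat(np.arange(len(centers)), spec.molecules_per_disc)
        return pos, ids, centers

    if spec.mode == "random":
        for ch in spec.channels:
            positions[ch], disc_ids[ch], disc_centers[ch] = _random_channel()
    elif spec.mode == "clustered_one_channel":
        centers = _pack_discs(rng, fov, spec.n_discs, spec.disc_radius_nm, spec.max_attempts)
        first, *rest = spec.channels
        positions[first], disc_ids[first], disc_centers[first] = _clustered_channel(centers)
        for ch in rest:
            positions[ch], disc_ids[ch], disc_centers[ch] = _random_channel()
    elif spec.mode == "clustered_both_independent":
        for ch in spec.channels:
            centers = _pack_discs(rng, fov, spec.n_discs, spec.disc_radius_nm, spec.max_attempts)
            positions[ch], disc_ids[ch], disc_centers[ch] = _clustered_channel(centers)
    else:  # co_clustered: both channels share disc centers
        centers = _pack_discs(rng, fov, spec.n_discs, spec.disc_radius_nm, spec.max_attempts)
        for ch in spec.channels:
            positions[ch], disc_ids[ch], disc_centers[ch] = _clustered_channel(centers)
    return SyntheticScene(spec, positions, disc_ids, disc_centers)


@dataclass
class BlinkModel:
    """Observation process mapping molecules to localization events.

    Each molecule receives ``Poisson(mean_observations / mean_burst_length)``
    bursts at uniform random start frames; a burst spans consecutive frames
    with geometric length (mean ``mean_burst_length``; 1 = memoryless single
    frames).  Every observation is displaced by isotropic Gaussian noise of
    ``localization_sigma`` (nm); sigma = 0 reproduces the molecule positions
    exactly.  Expected localizations per molecule = ``mean_observations``.
    """

    mean_observations: float = 20.0
    n_frames: int = 8000
    localization_sigma: float = 30.0
    mean_burst_length: float = 1.0

    def __post_init__(self):
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")
        if self.mean_burst_length < 1:
            raise ValueError("mean_burst_length must be >= 1")
        if self.n_frames < 1 or self.mean_observations <= 0:
            raise ValueError("invalid blink model")


def _sample_channel(rng, pos, disc, channel, blink: BlinkModel, exact_one=False) -> pd.DataFrame:
    n_mol = len(pos)
    p_stop = 1.0 / blink.mean_burst_length
    if exact_one:
        n_bursts = np.ones(n_mol, dtype=np.int64)
        lengths_per_burst = np.ones(n_mol, dtype=np.int64)
    else:
        n_bursts = rng.poisson(blink.mean_observations * p_stop, size=n_mol)
    rows_mol, rows_frame, rows_burst = [], [], []
    for i in range(n_mol):
        for b in range(n_bursts[i]):
            length = 1 if exact_one else rng.geometric(p_stop)
            start = rng.integers(0, blink.n_frames)
            frames = np.arange(start, min(start + length, blink.n_frames))
            rows_mol.append(np.full(len(frames), i, dtype=np.int64))
            rows_frame.append(frames)
            rows_burst.append(np.full(len(frames), b, dtype=np.int64))
    if rows_mol:
        mol = np.concatenate(rows_mol)
        frames = np.concatenate(rows_frame)
        burst = np.concatenate(rows_burst)
    else:
        mol = np.empty(0, dtype=np.int64)
        frames = np.empty(0, dtype=np.int64)
        burst = np.empty(0, dtype=np.int64)
    xy = pos[mol] + rng.normal(0.0, blink.localization_sigma, size=(len(mol), 2)) \
        if blink.localization_sigma > 0 else pos[mol].astype(float)
    return pd.DataFrame(
        {
            "x_nm": xy[:, 0] if len(mol) else np.empty(0),
            "y_nm": xy[:, 1] if len(mol) else np.empty(0),
            "frame": frames,
            "channel": channel,
            "sigma_nm": blink.localization_sigma,
            "molecule_id": mol,
            "disc_id": disc[mol] if len(mol) else np.empty(0, dtype=np.int64),
            "burst_id": burst,
        }
    )


def sample_localizations(
    scene: SyntheticScene,
    blink: BlinkModel,
    seed: int | None = None,
    mask: RoiMask | None = None,
    exact_one_observation: bool = False,
) -> LocalizationTable:
    """Sample a scene into a localization table under a blink model.

    Ground-truth ``molecule_id``/``disc_id``/``burst_id`` columns are retained
    (they are excluded from the standard CSV export).  If ``mask`` is given,
    localizations falling outside it are suppressed (probe-free topology).
    """
    rng = np.random.default_rng(scene.spec.seed + 1 if seed is None else seed)
    frames = [
        _sample_channel(rng, scene.positions[ch], scene.disc_ids[ch], ch, blink,
                        exact_one=exact_one_observation)
        for ch in scene.spec.channels
    ]
    df = pd.concat(frames, ignore_index=True)
    table = LocalizationTable(df, grouped=False, validate=False).canonical_sort()
    if mask is not None:
        keep = mask.contains(table.x, table.y)
        table = LocalizationTable(table.data[keep].copy(), grouped=False, validate=False)
    return table


# ---------------------------------------------------------------------------
# Ising-snapshot scenes
# ---------------------------------------------------------------------------


@dataclass
class IsingScene:
    """Point channels sampled from a lattice snapshot plus reference rasters."""

    locs: LocalizationTable  # channels: "protein", "probe"
    protein_raster: np.ndarray  # fully sampled channel-1 species raster
    probe_raster: np.ndarray  # fully sampled channel-2 species raster
    pixel_size: float  # nm
    blur_sigma: float  # nm applied to raster copies below
    protein_blurred: np.ndarray = None
    probe_blurred: np.ndarray = None


def sample_ising_scene(
    species: np.ndarray,
    spin: np.ndarray,
    probe_density_um2: float = 400.0,
    blur_sigma: float = 0.0,
    pixel_size: float = 2.0,
    protein: str = "receptor",
    probe_spin: int = -1,
    seed: int = 0,
    clustered_only: bool = False,
    cluster_center: tuple | None = None,
    cluster_radius_px: float | None = None,
) -> IsingScene:
    """Sample a lattice snapshot into a two-channel point scene.

    Channel 1 ("protein") carries the pixels of the chosen species (optionally
    restricted to a disc around the cluster center); channel 2 ("probe") is a
    random subset of the ``probe_spin`` spin class at ``probe_density_um2``
    (pass ``probe_density_um2=None`` for full sampling).  Points sit at pixel
    centers of the 2 nm lattice.  Gaussian blur (periodic wrap) of the rasters
    emulates 30 nm super-resolution precision or 220 nm diffraction-limited
    imaging; blur is applied to raster copies, leaving the point channels and
    fully sampled rasters untouched for oracle comparisons.
    """
    from .ising_signaling import SPECIES_CODES  # local import to avoid a cycle

    L = species.shape[0]
    code = SPECIES_CODES[protein]
    prot_mask = species == code
    if clustered_only:
        if cluster_center is None or cluster_radius_px is None:
            raise ValueError("clustered_only requires cluster_center and cluster_radius_px")
        yy, xx = np.mgrid[0:L, 0:L]
        disc = (yy - cluster_center[0]) ** 2 + (xx - cluster_center[1]) ** 2 <= cluster_radius_px**2
        prot_mask = prot_mask & disc
    probe_mask = (spin == probe_spin) & (species == 0)
    rng = np.random.default_rng(seed)
    prot_idx = np.flatnonzero(prot_mask)
    probe_idx = np.flatnonzero(probe_mask)
    if probe_density_um2 is not None:
        area_um2 = (L * pixel_size * 1e-3) ** 2
        n_probe = int(round(probe_density_um2 * area_um2))
        if n_probe > len(probe_idx):
            raise ValueError("probe density exceeds available pixels")
        probe_idx = rng.choice(probe_idx, size=n_probe, replace=False)
    rows = []
    for name, idx in (("protein", prot_idx), ("probe", probe_idx)):
        y, x = np.unravel_index(idx, (L, L))
        rows.append(
            pd.DataFrame(
                {
                    "x_nm": (x + 0.5) * pixel_size,
                    "y_nm": (y + 0.5) * pixel_size,
                    "frame": 0,
                    "channel": name,
                }
            )
        )
    locs = LocalizationTable(pd.concat(rows, ignore_index=True), validate=False)
    prot_raster = prot_mask.astype(float)
    probe_full = probe_mask.astype(float)
    scene = IsingScene(locs, prot_raster, probe_full, pixel_size, blur_sigma)
    if blur_sigma > 0:
        spx = blur_sigma / pixel_size
        scene.protein_blurred = ndimage.gaussian_filter(prot_raster, spx, mode="wrap", truncate=4.0)
        scene.probe_blurred = ndimage.gaussian_filter(probe_full, spx, mode="wrap", truncate=4.0)
    return scene


# ---------------------------------------------------------------------------
# topology masks and live streams
# ---------------------------------------------------------------------------


def generate_topology_mask(
    fov_nm: tuple,
    hole_center_nm: tuple | None = None,
    hole_radius_nm: float = 0.0,
    pixel_size: float = 25.0,
) -> tuple:
    """Loose/tight ROI pair for a field with a probe-free hole.

    The loose mask spans the full field (it *includes* the hole region, as a
    user would draw around a detached-membrane patch); the tight mask excludes
    the hole.  With no hole the two masks are identical.
    """
    loose = RoiMask.rectangle(fov_nm[0], fov_nm[1], pixel_size)
    if hole_radius_nm <= 0 or hole_center_nm is None:
        return loose, RoiMask(loose.mask.copy(), pixel_size)
    if not (0 <= hole_center_nm[0] <= fov_nm[0] and 0 <= hole_center_nm[1] <= fov_nm[1]):
        raise ValueError("hole must lie inside the field of view")
    ny, nx = loose.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy = hole_center_nm[1] / pixel_size - 0.5
    cx = hole_center_nm[0] / pixel_size - 0.5
    hole = (yy - cy) ** 2 + (xx - cx) ** 2 <= (hole_radius_nm / pixel_size) ** 2
    tight = loose.mask.copy()
    tight[hole] = False
    return loose, RoiMask(tight, pixel_size)


@dataclass
class BindingSpec:
    """Transiently bound sub-population near reference points.

    ``bound_fraction`` of probe molecules start bound to a uniformly chosen
    reference point: they diffuse with ``d_bound_um2_s`` and are tethered to
    within ``capture_radius_nm`` of their reference (reflected back inside).
    Reference points are re-emitted every frame as the "ref" channel.
    """

    reference_points_nm: np.ndarray = None
    bound_fraction: float = 0.0
    d_bound_um2_s: float = 0.1
    capture_radius_nm: float = 50.0


def generate_live_stream(
    n_molecules: int = 50,
    d_um2_s: float = 0.5,
    frame_interval_s: float = 0.02,
    n_frames: int = 200,
    fov_nm: tuple = (10000.0, 10000.0),
    localization_sigma: float = 30.0,
    p_observe: float = 1.0,
    binding: BindingSpec | None = None,
    seed: int = 0,
    channel: str = "probe",
) -> LocalizationTable:
    """Frame-resolved localizations of 2D Brownian molecules.

    Each molecule performs a random walk with per-frame step sd
    ``sqrt(2 D dt)`` per axis (reflecting boundaries), is observed each frame
    with probability ``p_observe`` and localized with Gaussian noise.  The
    mean squared frame-to-frame displacement of the localizations is
    ``4 D dt + 4 sigma_loc^2``.  With a :class:`BindingSpec`, a bound
    sub-population stays tethered near reference points, and reference
    localizations are emitted every frame as a second channel.
    """
    if d_um2_s < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    rng = np.random.default_rng(seed)
    step_sd = np.sqrt(2.0 * d_um2_s * frame_interval_s) * 1000.0  # nm
    pos = np.column_stack([rng.uniform(0, fov_nm[0], n_molecules), rng.uniform(0, fov_nm[1], n_molecules)])
    bound_to = np.full(n_molecules, -1, dtype=np.int64)
    if binding is not None and binding.bound_fraction > 0:
        refs = np.asarray(binding.reference_points_nm, dtype=float)
        n_bound = int(round(binding.bound_fraction * n_molecules))
        chosen = rng.choice(n_molecules, size=n_bound, replace=False)
        # round-robin assignment spreads bound molecules across references so
        # they do not pile within a linking radius of one another
        bound_to[chosen] = np.arange(n_bound) % len(refs)
        pos[chosen] = refs[bound_to[chosen]] + rng.uniform(
            -binding.capture_radius_nm / 2, binding.capture_radius_nm / 2, size=(n_bound, 2)
        )
        step_sd_bound = np.sqrt(2.0 * binding.d_bound_um2_s * frame_interval_s) * 1000.0
    rows = []
    for f in range(n_frames):
        if f > 0:
            free = bound_to < 0
            pos[free] += rng.normal(0.0, step_sd, size=(int(free.sum()), 2))
            if binding is not None and (~free).any():
                nb = int((~free).sum())
                pos[~free] += rng.normal(0.0, step_sd_bound, size=(nb, 2))
                # tether: reflect displacements that leave the capture radius
                refs = np.asarray(binding.reference_points_nm, dtype=float)
                delta = pos[~free] - refs[bound_to[~free]]
                dist = np.hypot(delta[:, 0], delta[:, 1])
                out = dist > binding.capture_radius_nm
                if out.any():
                    scale = (2 * binding.capture_radius_nm / dist[out] - 1.0)[:, None]
                    delta[out] = delta[out] * np.maximum(scale, -1.0)
                    pos[np.flatnonzero(~free)[out]] = refs[bound_to[~free][out]] + delta[out]
            # reflecting field-of-view boundaries
            for ax, lim in enumerate(fov_nm):
                pos[:, ax] = np.abs(pos[:, ax])
                pos[:, ax] = lim - np.abs(lim - pos[:, ax])
        seen = rng.uniform(size=n_molecules) < p_observe
        obs = pos[seen] + (
            rng.normal(0.0, localization_sigma, size=(int(seen.sum()), 2))
            if localization_sigma > 0
            else 0.0
        )
        rows.append(
            pd.DataFrame(
                {
                    "x_nm": obs[:, 0],
                    "y_nm": obs[:, 1],
                    "frame": f,
                    "channel": channel,
                    "sigma_nm": localization_sigma,
                    "molecule_id": np.flatnonzero(seen),
                    "bound": bound_to[seen] >= 0,
                }
            )
        )
        if binding is not None and binding.reference_points_nm is not None:
            refs = np.asarray(binding.reference_points_nm, dtype=float)
            ref_obs = refs + (
                rng.normal(0.0, localization_sigma, size=refs.shape)
                if localization_sigma > 0
                else 0.0
            )
            rows.append(
                pd.DataFrame(
                    {
                        "x_nm": ref_obs[:, 0],
                        "y_nm": ref_obs[:, 1],
                        "frame": f,
                        "channel": "ref",
                        "sigma_nm": localization_sigma,
                        "molecule_id": -1 - np.arange(len(refs)),
                        "bound": False,
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    return LocalizationTable(df, grouped=False, validate=False).canonical_sort()
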