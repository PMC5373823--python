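# Methods

This note records the models, estimators, numerical choices and known
limitations behind `phasecorr`. It states no empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates, rasters, binning

Localization coordinates are continuous nanometres, origin at the lower-left
corner of the field of view. Rasters use half-open pixel bins
`[k·p, (k+1)·p)` with `p = 25 nm` by default (the reconstruction pixel).
Radial bins are `[k·Δr, (k+1)·Δr)` with `Δr = 25 nm`, centers at
`(k + ½)Δr`; the first bin is labeled `r < 25 nm`. All correction factors
that depend on `r` are evaluated at bin centers.

## Cross-correlation with ROI-aware normalization

For channels A and B restricted to a binary ROI mask M, the pair count at
integer pixel lag `d` is the discrete cross-correlation of the masked count
images; the expected count under a random co-distribution is
`N_A·N_B·M⋆M(d)/S²` where `M⋆M` is the mask autocorrelation and `S` the
mask pixel count. `C(r)` is the ratio of annulus-summed counts to
annulus-summed expectations. This normalization makes `C ≡ 1` for random
co-distributions under any mask shape, including masks with interior holes
(membrane detached from the coverslip); conversely, analyzing a probe-free
hole *inside* the ROI produces the long-range `C > 1` artifact the tight
mask removes — both behaviors are test-pinned.

Two routes produce the identical result: an FFT route (zero-padded, or
cyclic for periodic lattice scenes) and a direct route that histograms
explicit A–B pairs. The direct route measures pair separations between the
centers of the containing raster pixels and shares the mask-autocorrelation
expectation, so the routes agree to floating-point rounding (~1e-16
relative; asserted at 1e-6). Cross-channel correlation is computed from
*ungrouped* localizations: overcounting multiplies both the measured and the
expected pair counts by the same factors and cancels in C(r) (duplicating
every localization k-fold leaves C unchanged, asserted exactly).

## Overcounting-robust density (autocorrelation fit)

A reversibly photoswitching label yields `m` localizations per molecule
scattered with the localization precision; the single-channel
autocorrelation then carries a same-molecule peak whose area is `1/ρ` when
`m` is Poisson. We fit `G(r) = 1 + A·exp(−r²/2σ²)` and report
`ρ = 1/(2πσ²A)` in µm⁻². Numerical choices:

- input is *grouped* data (sequential-frame merging, 80 nm radius), which
  brings per-molecule counts close to Poisson;
- the fit uses the per-lag-pixel autocorrelation at exact lag radii rather
  than 25 nm ring averages — ring-averaging a steep Gaussian over the
  unevenly spaced lags inside an annulus biases the fitted area (and hence
  ρ) by 10–20%;
- zero-lag self pairs are removed; default fit window 50–500 nm; least
  squares with positivity bounds on A and σ.

For clustered species the estimate is the density of independent clusters,
not molecules (the README example demonstrates this on a co-clustered
scene). Recovery within 10% holds across 2–20 µm⁻² and 10–50
observations/molecule for random scenes, and is invariant to doubling the
observation count (test-pinned).

## Variance model

`dC_raw(r)` is the SEM of the per-pixel normalized correlogram over each
annulus. The precision correction

`dC1(r) = (1 + 2σ_PSF/Δr)(1 + e^{−r²/4σ_PSF²})·dC_raw(r)`, σ_PSF = 30 nm,

compensates the pixel-to-pixel correlation a smooth super-resolved PSF
induces; the sampling correction

`dC2(r) = dC1(r) − (4πσ_PSF²/Δr²)(N₁²/n₁ + N₂²/n₂)⁻¹(1 + 4e^{−r²/4σ_PSF²})`

subtracts the part contributed by under-sampling of the PSF, with `n₁, n₂`
the emitter counts from the density fit × ROI area. dC2 is floored at zero
(a variance cannot be negative); the first bin is flagged unreliable.

**Calibration, measured.** Across 100 replicate random scenes at 20
observations/molecule, the mean dC2 tracks the across-replicate scatter of
C(r) to within ~10–50% per bin, erring on the conservative side
(overestimating the error). The multiplicative factor assumes a fully
smoothed correlogram; at ~20 samples per emitter the pair kernel is only
partially sampled, so the ideal factor is somewhat smaller than
`1 + 2σ_PSF/Δr`, and the subtractive term — which scales as `n/N²` — is far
too small to close that gap until sampling drops to a few observations per
molecule. At ~2 observations/molecule dC2 is closer to the empirical
scatter than dC1, as intended. Practical consequence: single-cell error
bars from dC2 are mildly conservative for well-sampled data. The
acceptance suite reports the measured calibration ratios rather than hiding
them.

## Drift correction and grouping

Drift is estimated every 500 frames: block images (25 nm pixels, lightly
smoothed with σ = 1 px so the sparse-count correlation peak supports a 3×3
parabolic sub-pixel fit) are cross-correlated between successive blocks;
shifts are accumulated, assigned to block midpoints, linearly interpolated
per frame and subtracted. Blocks with too few localizations are
interpolated from neighbors with a warning. The estimator is
translation-equivariant and recovers injected linear drift within one
raster pixel (test-pinned); rotation is outside the motion model and shows
up as residual error.

Grouping merges chains of localizations appearing in *consecutive* frames
within 80 nm of the open chain's running mean; the chain emits one
localization at the chain mean with the first frame index. Re-activations
after a frame gap are intentionally not merged. Grouping is idempotent.

## Live-cell steady state and tracking

Frame-pair cross-correlations are accumulated for all `|Δframe| ≤ τ_max`
(default 50) in both channel orders and averaged with equal per-τ weight.
The average is divided by the cross-correlation of the two channels' masked
average images blurred with a truncated (±4σ) Gaussian of σ = 1 µm, which
removes structure larger than ~1 µm (edge-brightened labeling gradients)
while preserving sub-micron correlation. Whether the divisor is the
correlation or the product of the blurred averages is not uniquely
determined by the source description; the correlation form is implemented
(flagged here).

The tracker links localizations to trajectory heads greedily within 500 nm
in the next frame; any ambiguity — two candidates for one head or two heads
claiming one candidate — terminates every trajectory involved, so no
localization joins two trajectories and no recorded step exceeds the
linking radius (asserted exactly). `MSD(nΔt) = 4DnΔt + 4σ_loc²` fits over
lags 1–4 recover D within 10% at D = 0.5 µm²/s, 20 ms frames, σ_loc = 30 nm.
Reference-proximal steps (within 100 nm of a simultaneous reference
localization, steps to the immediately preceding/following points) detect a
5×-slowed bound subpopulation by two-sample KS and return a null result
when proximal probes keep full mobility.

## Membrane Ising model

Conserved-order-parameter Ising model, L×L periodic square lattice
(default 256; 1 px = 2 nm), `H = −Σ_{⟨ij⟩} S_i S_j − Σ_i R_i Φ^R_i` (or
`−Σ_i S_i Φ^D_i` for stabilized-domain runs), `T = 1.05·T_C` with
`T_C = 2/ln(1+√2)`. Composition: 50 receptors (+1), 100 kinases (+1), 100
phosphatases (−1), background split ordered/disordered by the ordered
fraction (default 0.5; uniform membranes set it to 0). Kawasaki exchanges:
non-local pairs for equilibration, nearest-neighbor for production
(diffusive dynamics; one sweep = L² proposed swaps ≈ 1 µs). Exchanges move
spin, species identity and phosphorylation flag together, so all totals are
conserved exactly. Metropolis acceptance uses the analytic ΔH of the
exchange (the shared bond of adjacent pairs contributes a constant);
local and non-local sampling agree in equilibrium energy distribution
(replicate-mean KS test), and an auxiliary single-spin-flip sampler
validates the critical constant by Binder-cumulant crossings on
L ∈ {16, 32, 64} (within 2%).

**Receptor trap.** The clustering field acts only on receptors inside a
16 px (32 nm) disc. The trap must beat the translational entropy of the
lattice (~ln(L²/disc) ≈ 4.4 k_BT at L = 256, where a 5-coupling trap holds
only a minority of receptors); magnitude 20 keeps ≥90% of receptors inside
the disc at T = 1.05 T_C — receptors are effectively confined to the cluster
while still exchanging with the surroundings. The
domain field (radius 24 or 48 px) has magnitude 1 — one interaction — and
couples to all spins; domain-field runs carry 200 receptors to represent
the many phosphorylatable membrane proteins.

**Reactions.** On every accepted exchange, the two moved sites and any
receptor in their 4-neighborhoods are evaluated: each adjacent kinase gives
a 0.1% phosphorylation draw, each adjacent phosphorylated receptor (if the
receptor-bound-kinase feedback is enabled) a 0.1% draw, and an adjacent
phosphatase dephosphorylates with probability 1, applied last so
phosphatase contact dominates simultaneous adjacency within one update.
Reactions fire only on accepted moves, never for static configurations.

**Protocols.** Production runs of the clustering comparison switch the trap
on at t = 0 after a field-free non-local equilibration (default here
500–10,000 sweeps depending on scale) and record the response transient —
this is the regime in which a uniform membrane shows essentially no
activation. At true equilibrium the distinction partially collapses: the
confined 50-receptor droplet is itself an ordered patch that slowly
collects kinases even in an all-disordered membrane, so the
uniform-membrane contrast is a statement about the signaling response
window after clustering, not about t → ∞. The composition sweep and the
domain-size comparison, whose phenomena are properties of the clustered
steady state (receptors confined / domain stabilized throughout), run with
the field on during equilibration. Both protocols are exposed
(`field_schedule ∈ {on_at_t0, equilibrated, off}`).

**Scale used in validation.** Orderings are checked at L = 128 with 500
equilibration + 2000 production sweeps over 10 seeds — small enough to run
on one CPU in minutes, large enough that the orderings (heterogeneous+RBK >
heterogeneous−RBK > uniform+RBK; ordered fraction 0.2 > 0.5 > 0.8; domain
48 px > 24 px) are stable. Phosphorylation levels are reported as the
fraction of receptors phosphorylated, averaged over the second half of the
production trace.

**Snapshot correlations.** Species rasters from trajectory snapshots are
cross-correlated with periodic boundaries; finite lateral resolution is
emulated by Gaussian-blurring both rasters (wrap mode, ±4σ kernel), which
is equivalent to convolving the 2D correlogram with the PSF
autocorrelation. Kinase enrichment and phosphatase exclusion at clustered
receptors are attenuated but keep their sign under 30 nm blur; 220 nm
(diffraction-limited) blur removes the depletion signal almost entirely.
Sparse probe sampling at 400 µm⁻² reproduces the fully sampled correlation
within paired error bounds across 100 snapshots.

## Synthetic data: what it emulates, what it does not

The generators emulate molecule layouts (random / clustered / co-clustered
in non-overlapping discs, rejection-packed with a 10⁵-attempt cap),
blinking as a per-molecule burst process (Poisson burst count, geometric
burst length, uniform burst starts; default mean burst length 1 frame,
i.e. memoryless — the temporal correlation structure of real
photoswitching is not known in detail and is configurable), isotropic
Gaussian localization noise (default 30 nm), 5000–10,000-frame
acquisitions with 10–50 observations per molecule, probe densities
2–20 µm⁻², ROI topology holes, and 2D Brownian live streams with an
optional tethered sub-population (round-robin reference assignment so
bound molecules do not pile inside a linking radius). Deliberately not
modeled: camera noise, PSF overlap and multi-emitter fitting failures,
dipole/astigmatism effects, fluorophore spectral crosstalk, and real
photophysics beyond observation-count statistics. Tests passing on these
generators therefore validate the *estimators* under their stated
assumptions, not the upstream localization step.

Every generated table carries ground-truth ids (molecule, disc, burst,
bound state) so tests can join localizations back to the truth; ids are
excluded from the standard CSV export.

## Validation scale choices

The acceptance checks use: 100 cells of 10 µm⁻² × 10×10 µm for the
normalization property; 100 replicates of 5×5 µm scenes for variance
calibration; 3 seeds per condition for density recovery; 100 snapshots of
an L = 256 trajectory for the sampling/blur bridge; 10 seeds ×
(500 + 2000) sweeps at L = 128 for the phosphorylation orderings; ~15,000
steps for tracker recovery. These sizes are the package's own choices for
a single-CPU validation run; all estimators accept larger inputs.

## Known limitations

- The dC1/dC2 variance model is conservative (~tens of percent) for
  well-sampled bursty data, as measured above.
- The density estimator assumes near-random emitter positions; for
  clustered species it reports cluster density by design.
- Drift correction models pure translation per 500-frame block.
- The tracker is deliberately conservative; in dense scenes it fragments
  trajectories rather than risk misassignment, biasing step statistics
  toward isolated molecules.
- The Ising model has a single receptor cluster, no hydrodynamics, no
  continuum limit, and its coupling units are not mapped to physical free
  energies beyond the T/T_C convention.
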